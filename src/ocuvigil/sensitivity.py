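"""Robustness checks: three perturbations of the baseline analysis.

1. exclusion of ocular-event reports with heavy missingness (≥ half of
   age / weight / concomitant-medication information absent);
2. stratification of the study window into two reporting periods;
3. exclusion of ocular-event reports carrying a concomitant drug with
   known ocular toxicity, with the regression refitted.

Each run is a pure function of the baseline pipeline state plus its
perturbation parameters and reports indicator drift against the baseline;
an indicator is judged consistent when it moved by less than the
configured relative threshold (5% by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io_faers, meddra, riskmodel, signals
from .errors import ConfigurationError

#: illustrative, user-replaceable list of co-medications with documented
#: ocular toxicity
DEFAULT_OCULAR_RISK_DRUGS: tuple[str, ...] = (
    "TAMOXIFEN",
    "HYDROXYCHLOROQUINE",
    "CHLOROQUINE",
    "AMIODARONE",
    "ETHAMBUTOL",
    "ISOTRETINOIN",
    "DIGOXIN",
)


def _consistency(original: float, new: float, threshold: float) -> str:
    if not np.isfinite(original) or not np.isfinite(new) or original == 0:
        return "Not evaluable"
    return "Consistent" if abs(new / original - 1) < threshold else "Inconsistent"


def _incidence_by_drug(cohort_frame: pd.DataFrame) -> pd.Series:
    """Percentage of each drug's reports that are ocular-event reports."""
    per_drug = cohort_frame.groupby("drug")["oae"].mean() * 100
    per_drug["all"] = cohort_frame["oae"].mean() * 100
    return per_drug


def _recompute_signals(state, keep_ids: set, background_ids: set | None = None) -> pd.DataFrame:
    cohort_cases = state.cohort.cohort_cases
    cohort_cases = cohort_cases[cohort_cases["primaryid"].isin(keep_ids)]
    background = state.cohort.background_cases
    if background_ids is not None:
        background = background[background["primaryid"].isin(background_ids)]
    events = state.events[state.events["primaryid"].isin(
        set(cohort_cases["primaryid"]) | set(background["primaryid"])
    )]
    ocular = sorted(set(events.loc[events["soc"] == meddra.OCULAR_SOC, "pt"]))
    tables = signals.contingency_tables(
        cohort_cases,
        events,
        background,
        pts=ocular,
    )
    return signals.disproportionality(tables, state.config.signal_rules)


def _high_missing_mask(frame: pd.DataFrame, threshold: float) -> pd.Series:
    missing = pd.DataFrame(
        {
            "age": frame["age_years"].isna(),
            "weight": frame["weight_kg"].isna(),
            "concomitant": frame["n_concomitant"] == 0,
        }
    )
    return missing.mean(axis=1) >= threshold


def run_missingness_exclusion(state, threshold: float = 0.5) -> dict:
    """Drop reports missing ≥ ``threshold`` of the three information
    fields (age, weight, concomitant medications) from the whole analysis
    set, then recompute ocular-event incidence and signals.

    Concomitant-medication information counts as missing when the report
    carries no co-medication rows at all (spontaneous reports cannot
    distinguish "none taken" from "not recorded").  The exclusion applies
    to cohort and comparator reports alike, so that under
    outcome-independent missingness every indicator stays unbiased.
    """
    cf = state.cohort_frame()
    high_missing = _high_missing_mask(cf, threshold)
    excluded = cf[high_missing]
    kept = cf[~high_missing]

    bg = state.cohort.background_cases
    bg_conco = (
        bg["n_concomitant"]
        if "n_concomitant" in bg.columns
        else pd.Series(0, index=bg.index)
    )
    bg_missing = _high_missing_mask(bg.assign(n_concomitant=bg_conco), threshold)
    bg_kept_ids = set(bg.loc[~bg_missing, "primaryid"])

    base_inc = _incidence_by_drug(cf)
    new_inc = _incidence_by_drug(kept)

    if kept.empty:
        return {"empty": True, "n_excluded": int(len(excluded))}

    new_signals = _recompute_signals(state, set(kept["primaryid"]), bg_kept_ids)
    base_pos = int(state.signal_results["positive_signal"].sum())
    new_pos = int(new_signals["positive_signal"].sum())

    rows = []
    for drug in base_inc.index:
        orig, new = float(base_inc[drug]), float(new_inc.get(drug, np.nan))
        rows.append(
            {
                "scenario": "missingness_exclusion",
                "indicator": f"{drug} OAE incidence (%)",
                "original": orig,
                "sensitivity": new,
                "consistency": _consistency(orig, new, 0.05),
            }
        )
    rows.append(
        {
            "scenario": "missingness_exclusion",
            "indicator": "positive signals (count)",
            "original": base_pos,
            "sensitivity": new_pos,
            "consistency": _consistency(base_pos, new_pos, 0.05),
        }
    )
    return {
        "n_excluded": int(len(excluded)),
        "incidence": new_inc,
        "signals": new_signals,
        "drift": pd.DataFrame(rows),
    }


def run_period_stratification(state, split_year: int = 2020) -> dict:
    """Analyze the two reporting periods (before / from ``split_year``)
    independently; report per-period signals and the Ribociclib-vs-
    Abemaciclib odds-ratio contrast."""
    cf = state.cohort_frame()
    periods = {
        f"<{split_year}": cf[cf["report_year"] < split_year],
        f">={split_year}": cf[cf["report_year"] >= split_year],
    }
    out: dict = {"periods": {}}
    for label, sub in periods.items():
        entry: dict = {"n": int(len(sub))}
        if sub.empty:
            entry["empty"] = True
            out["periods"][label] = entry
            continue
        entry["signals"] = _recompute_signals(state, set(sub["primaryid"]))
        try:
            fit = riskmodel.fit_logistic(sub, state.config.regression_spec)
            ribo = fit.terms[fit.terms["term"] == "drug_Ribociclib"]
            entry["ribociclib_vs_abemaciclib_or"] = (
                float(ribo["odds_ratio"].iloc[0]) if len(ribo) else np.nan
            )
            entry["regression"] = fit
        except ConfigurationError:
            entry["ribociclib_vs_abemaciclib_or"] = np.nan
        out["periods"][label] = entry

    ors = {
        label: entry.get("ribociclib_vs_abemaciclib_or", np.nan)
        for label, entry in out["periods"].items()
    }
    base = state.regression.terms
    base_or = base.loc[base["term"] == "drug_Ribociclib", "odds_ratio"]
    base_or = float(base_or.iloc[0]) if len(base_or) else np.nan
    rows = [
        {
            "scenario": "period_stratification",
            "indicator": f"Ribociclib vs Abemaciclib OR ({label})",
            "original": base_or,
            "sensitivity": val,
            "consistency": _consistency(base_or, val, 0.05),
        }
        for label, val in ors.items()
    ]
    out["drift"] = pd.DataFrame(rows)
    return out


def run_codrug_exclusion(
    state,
    ocular_risk_drugs=DEFAULT_OCULAR_RISK_DRUGS,
    only_oae: bool = True,
    or_threshold: float = 0.05,
) -> dict:
    """Exclude (ocular-event) reports with a listed high-risk concomitant
    drug and refit the regression; drift per model term."""
    drug_list = [io_faers.clean_name(d) for d in ocular_risk_drugs if str(d).strip()]
    if not drug_list:
        raise ConfigurationError("ocular_risk_drugs must be non-empty")

    cf = state.cohort_frame()
    exp = state.cohort.exposures
    exp = exp[exp["primaryid"].isin(cf["primaryid"])]
    names = exp["drugname"].map(io_faers.clean_name)
    hit = np.zeros(len(exp), dtype=bool)
    for d in drug_list:
        hit |= names.str.contains(d, regex=False).to_numpy()
    flagged_ids = set(exp.loc[hit, "primaryid"])

    mask = cf["primaryid"].isin(flagged_ids)
    if only_oae:
        mask &= cf["oae"] == 1
    excluded = cf[mask]
    kept = cf[~mask]

    refit = riskmodel.fit_logistic(kept, state.config.regression_spec)
    base = state.regression.terms.set_index("term")["odds_ratio"]
    new = refit.terms.set_index("term")["odds_ratio"]
    rows = []
    for term in base.index:
        orig = float(base[term])
        val = float(new.get(term, np.nan))
        rows.append(
            {
                "scenario": "codrug_exclusion",
                "indicator": f"{term} OR",
                "original": orig,
                "sensitivity": val,
                "consistency": _consistency(orig, val, or_threshold),
            }
        )
    log = excluded[["primaryid", "drug"]].copy()
    return {
        "n_excluded": int(len(excluded)),
        "exclusion_log": log,
        "regression": refit,
        "drift": pd.DataFrame(rows),
    }
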