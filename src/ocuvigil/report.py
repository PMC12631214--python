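"""Stratified demographic tables (per-drug columns plus the combined
class), mirroring the layout of spontaneous-report cohort descriptions:
counts with percentages of each drug's column total, missing rows always
shown, numeric fields summarised as mean (SD) / median (Q1, Q3) / min–max.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_BIN_EDGES = [-np.inf, 18, 30, 50, 65, 76, 86, np.inf]
AGE_BIN_LABELS = ["<18", "18-29", "30-49", "50-64", "65-75", "76-85", ">85"]

WEIGHT_BIN_EDGES = [-np.inf, 50, 70, 90, np.inf]
WEIGHT_BIN_LABELS = ["<50 kg", "50-70 kg", "70-90 kg", ">=90 kg"]


def _strata_counts(values: pd.Series, order: list[str]) -> pd.Series:
    counts = values.value_counts()
    return pd.Series({level: int(counts.get(level, 0)) for level in order})


def _categorise(cases: pd.DataFrame) -> dict[str, pd.Series]:
    sex = cases["sex"].map({"F": "Female", "M": "Male"}).fillna("Missing")
    sex[cases["sex"].isin(["", None])] = "Missing"

    age = pd.cut(
        cases["age_years"], AGE_BIN_EDGES, labels=AGE_BIN_LABELS, right=False
    ).astype(object)
    age = pd.Series(age, index=cases.index).fillna("Missing")

    year = cases["report_year"].astype("Float64")
    year_lab = year.astype(object).map(
        lambda v: str(int(v)) if pd.notna(v) else "Missing"
    )

    reporter = cases["reporter_type"].replace("", "Missing")

    conco = np.where(cases["n_concomitant"] >= 5, ">=5", "<5")

    weight = pd.cut(
        cases["weight_kg"], WEIGHT_BIN_EDGES, labels=WEIGHT_BIN_LABELS, right=False
    ).astype(object)
    weight = pd.Series(weight, index=cases.index).fillna("Missing")

    # death folds into the serious row for the severity stratum
    outcome = cases["outcome_class"].map(
        {
            "non_serious": "Non-serious",
            "serious": "Serious",
            "death": "Serious",
            "missing": "Missing",
        }
    ).fillna("Missing")

    return {
        "sex": sex,
        "age_group": age,
        "report_year": year_lab,
        "region": cases["region"],
        "reporter_type": reporter,
        "n_concomitant": pd.Series(conco, index=cases.index),
        "weight": weight,
        "outcome_severity": outcome,
    }


def demographic_table(
    cohort_cases: pd.DataFrame,
    tto: pd.DataFrame | None = None,
    combined_label: str = "CDK4/6 inhibitors",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the stratified table and the numeric summaries.

    Returns ``(strata, numeric)``: ``strata`` is long-format with columns
    ``section, level, drug, n, pct`` (percentages of the drug column's
    total, one decimal); ``numeric`` holds mean/SD/median/Q1/Q3/min/max
    for concomitant count, weight, and time to onset, plus the onset
    missing count.
    """
    cases = cohort_cases.copy()
    if tto is not None:
        cases = cases.merge(tto, on="primaryid", how="left")
    elif "tto_days" not in cases.columns:
        cases["tto_days"] = np.nan

    columns = {combined_label: cases}
    for drug, sub in cases.groupby("drug"):
        columns[str(drug)] = sub

    strata_rows = []
    numeric_rows = []
    for drug, sub in columns.items():
        total = len(sub)
        strata_rows.append(
            {"section": "total", "level": "Total", "drug": drug, "n": total, "pct": 100.0}
        )
        cats = _categorise(sub)
        for section, values in cats.items():
            # missing row always shown, and always last
            levels = sorted(set(values.astype(str)) - {"Missing"}) + ["Missing"]
            counts = _strata_counts(values.astype(str), levels)
            for level, n in counts.items():
                pct = round(100 * n / total, 1) if total else np.nan
                strata_rows.append(
                    {
                        "section": section,
                        "level": level,
                        "drug": drug,
                        "n": int(n),
                        "pct": pct,
                    }
                )
        for name, series in (
            ("n_concomitant", sub["n_concomitant"].astype(float)),
            ("weight_kg", sub["weight_kg"]),
            ("tto_days", sub["tto_days"]),
        ):
            vals = series.dropna().to_numpy(float)
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                numeric_rows.append(
                    {
                        "variable": name,
                        "drug": drug,
                        "n": len(vals),
                        "n_missing": int(series.isna().sum()),
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                        "median": float(med),
                        "q1": float(q1),
                        "q3": float(q3),
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                    }
                )
            else:
                numeric_rows.append(
                    {
                        "variable": name,
                        "drug": drug,
                        "n": 0,
                        "n_missing": int(series.isna().sum()),
                        "mean": np.nan, "sd": np.nan, "median": np.nan,
                        "q1": np.nan, "q3": np.nan, "min": np.nan, "max": np.nan,
                    }
                )
    strata = pd.DataFrame(strata_rows)
    numeric = pd.DataFrame(numeric_rows)
    return strata, numeric
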