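"""Multivariable logistic regression for ocular-event reporting.

Within the drug cohort, the outcome is binary per report: does the report
carry any ocular Preferred Term?  The four core covariates are age ≥ 65
(reference < 65), drug (reference Abemaciclib), concomitant-medication
burden in categories 0 / 1–5 / >5 (reference 0), and concomitant letrozole
use (reference no).  The fit is maximum likelihood with Wald intervals on
the odds-ratio scale; multicollinearity is screened with variance
inflation factors and calibration with the Hosmer–Lemeshow test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError


@dataclass(frozen=True)
class RegressionSpec:
    """Model specification with fixed reference levels."""

    drug_reference: str = "Abemaciclib"
    drug_levels: tuple[str, ...] = ("Palbociclib", "Ribociclib")
    age_cut: float = 65.0
    concomitant_bins: tuple[float, float] = (0.0, 5.0)  # 0 | 1–5 | >5
    selection: str = "none"  # or "backward"
    alpha_stay: float = 0.05
    covariates: tuple[str, ...] = ("age_ge_65", "drug", "n_concomitant_cat", "letrozole_use")


@dataclass
class RegressionResult:
    """Fit summary: per-term odds ratios, diagnostics, selection trace."""

    terms: pd.DataFrame  # term, odds_ratio, ci_low, ci_high, p_value
    vif: pd.Series
    hl_statistic: float
    hl_p: float
    n_used: int
    n_excluded: int
    converged: bool
    selection_trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    model: object | None = None
    design: pd.DataFrame | None = None


def build_design(
    data: pd.DataFrame, spec: RegressionSpec = RegressionSpec()
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]], int]:
    """Dummy-coded design matrix with fixed references; complete cases only.

    Returns (X, y, term→columns map, n_excluded).  ``data`` needs columns
    ``oae`` (0/1), ``age_years``, ``drug``, ``n_concomitant``,
    ``letrozole_use``.
    """
    needed = ["oae", "age_years", "drug", "n_concomitant", "letrozole_use"]
    df = data[needed].copy()
    n0 = len(df)
    df = df.dropna()
    df = df[df["drug"].isin((spec.drug_reference,) + spec.drug_levels)]
    n_excluded = n0 - len(df)

    X = pd.DataFrame(index=df.index)
    groups: dict[str, list[str]] = {}
    if "age_ge_65" in spec.covariates:
        X["age_ge_65"] = (df["age_years"] >= spec.age_cut).astype(float)
        groups["age_ge_65"] = ["age_ge_65"]
    if "drug" in spec.covariates:
        cols = []
        for level in spec.drug_levels:
            col = f"drug_{level}"
            X[col] = (df["drug"] == level).astype(float)
            cols.append(col)
        groups["drug"] = cols
    if "n_concomitant_cat" in spec.covariates:
        lo, hi = spec.concomitant_bins
        nc = df["n_concomitant"].astype(float)
        X["conco_1_5"] = ((nc > lo) & (nc <= hi)).astype(float)
        X["conco_gt5"] = (nc > hi).astype(float)
        groups["n_concomitant_cat"] = ["conco_1_5", "conco_gt5"]
    if "letrozole_use" in spec.covariates:
        X["letrozole_use"] = df["letrozole_use"].astype(float)
        groups["letrozole_use"] = ["letrozole_use"]
    y = df["oae"].astype(float)
    return X, y, groups, n_excluded


def _fit_mle(X: pd.DataFrame, y: pd.Series):
    import warnings as _warnings

    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            fit = model.fit(disp=0, maxiter=200)
        except Exception:  # separation / singular designs
            return None, False
        converged = bool(fit.mle_retvals.get("converged", True))
        if any("separation" in str(w.message).lower() for w in caught):
            converged = False
    return fit, converged


def fit_logistic(
    data: pd.DataFrame, spec: RegressionSpec = RegressionSpec()
) -> RegressionResult:
    """Maximum-likelihood logistic fit with optional backward selection.

    Backward selection drops, one at a time, the covariate group with the
    largest likelihood-ratio p-value until all remaining groups have
    p < ``alpha_stay``; the drug term (the exposure of interest) is never
    dropped.  Zero-variance columns are removed with a warning.
    Non-convergence (e.g. separation) yields a flagged result, not an
    exception.
    """
    X, y, groups, n_excluded = build_design(data, spec)
    warnings: list[str] = []
    if y.nunique() < 2:
        raise ConfigurationError("outcome must have both events and non-events")

    for term, cols in list(groups.items()):
        keep = [c for c in cols if X[c].std() > 0]
        dropped = set(cols) - set(keep)
        if dropped:
            warnings.append(f"dropped zero-variance columns: {sorted(dropped)}")
            X = X.drop(columns=list(dropped))
            if keep:
                groups[term] = keep
            else:
                del groups[term]

    trace: list[dict] = []
    if spec.selection == "backward":
        while True:
            fit, conv = _fit_mle(X, y)
            if fit is None:
                break
            worst_term, worst_p = None, -1.0
            for term, cols in groups.items():
                if term == "drug":
                    continue
                reduced, rconv = _fit_mle(X.drop(columns=cols), y)
                if reduced is None:
                    continue
                lr = 2 * (fit.llf - reduced.llf)
                p = stats.chi2.sf(max(lr, 0.0), df=len(cols))
                if p > worst_p:
                    worst_term, worst_p = term, p
            if worst_term is None or worst_p <= spec.alpha_stay:
                break
            trace.append({"dropped": worst_term, "p_value": worst_p})
            X = X.drop(columns=groups.pop(worst_term))
    elif spec.selection != "none":
        raise ConfigurationError(f"unknown selection {spec.selection!r}")

    fit, converged = _fit_mle(X, y)
    if fit is None:
        return RegressionResult(
            terms=pd.DataFrame(
                columns=["term", "odds_ratio", "ci_low", "ci_high", "p_value"]
            ),
            vif=pd.Series(dtype=float),
            hl_statistic=np.nan,
            hl_p=np.nan,
            n_used=len(y),
            n_excluded=n_excluded,
            converged=False,
            selection_trace=trace,
            warnings=warnings + ["fit failed (separation or singular design)"],
        )

    params = fit.params.drop("const")
    ci = fit.conf_int().drop("const")
    with np.errstate(over="ignore"):  # unbounded CI under near-separation
        terms = pd.DataFrame(
            {
                "term": params.index,
                "odds_ratio": np.exp(params.to_numpy()),
                "ci_low": np.exp(ci[0].to_numpy()),
                "ci_high": np.exp(ci[1].to_numpy()),
                "p_value": fit.pvalues.drop("const").to_numpy(),
            }
        ).reset_index(drop=True)

    vif = compute_vif(X)
    hl_stat, hl_p = hosmer_lemeshow(y.to_numpy(), fit.predict())
    return RegressionResult(
        terms=terms,
        vif=vif,
        hl_statistic=hl_stat,
        hl_p=hl_p,
        n_used=len(y),
        n_excluded=n_excluded,
        converged=converged,
        selection_trace=trace,
        warnings=warnings,
        model=fit,
        design=X,
    )


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors via auxiliary regressions.

    Each column is regressed (with intercept) on all the others;
    VIF = 1 / (1 − R²), infinite under perfect collinearity.
    """
    vif = {}
    Xv = X.to_numpy(float)
    n = Xv.shape[0]
    for j, col in enumerate(X.columns):
        yj = Xv[:, j]
        others = np.delete(Xv, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            vif[col] = np.nan
        elif ss_res / ss_tot < 1e-12:
            vif[col] = np.inf
        else:
            vif[col] = 1.0 / (ss_res / ss_tot)
    return pd.Series(vif, name="vif")


def hosmer_lemeshow(
    y: np.ndarray, p_hat: np.ndarray, g: int = 10
) -> tuple[float, float]:
    """Hosmer–Lemeshow goodness-of-fit χ² over ``g`` risk groups.

    Groups are deciles of predicted risk with ties kept together; the
    statistic is referred to χ² with ``g − 2`` degrees of freedom.
    """
    if g < 3:
        raise ConfigurationError("hosmer_lemeshow requires g >= 3")
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    try:
        bins = pd.qcut(p_hat, q=g, duplicates="drop")
    except ValueError:
        return np.nan, np.nan
    frame = pd.DataFrame({"y": y, "p": p_hat, "bin": bins})
    grouped = frame.groupby("bin", observed=True)
    obs1 = grouped["y"].sum().to_numpy()
    exp1 = grouped["p"].sum().to_numpy()
    size = grouped.size().to_numpy().astype(float)
    obs0 = size - obs1
    exp0 = size - exp1
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (obs1 - exp1) ** 2 / exp1 + (obs0 - exp0) ** 2 / exp0
    stat = float(np.nansum(contrib))
    df = len(size) - 2
    if df <= 0:
        return stat, np.nan
    return stat, float(stats.chi2.sf(stat, df=df))


def forest_table(result: RegressionResult) -> pd.DataFrame:
    """Plot-ready (term, OR, low, high, p) rows for a forest plot."""
    return result.terms.rename(
        columns={"odds_ratio": "or", "ci_low": "low", "ci_high": "high", "p_value": "p"}
    )
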