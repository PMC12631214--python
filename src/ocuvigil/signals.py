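"""Disproportionality analysis on drug × event 2×2 tables.

For each (drug, Preferred Term) pair the four-fold table is

====  ==========================  ==========================
      target event                other events
====  ==========================  ==========================
drug  a                           b
rest  c                           d
====  ==========================  ==========================

counted over deduplicated reports (a report counts once per cell).  Three
statistics are computed:

* **ROR** — reporting odds ratio ``ad / bc`` with a Woolf (log-scale)
  confidence interval ``exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d))``;
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  1-df χ² test of the table (Yates continuity correction by default);
* **BCPNN information component** — ``IC = log2`` of the observed-to-
  expected reporting ratio under the Bayesian model of Bate et al., either
  in closed form (posterior expectation and variance, ``IC025 = E[IC] −
  1.96·√V[IC]``) or by Monte-Carlo sampling of the posterior.

Signal calling uses configurable thresholds; the frequentist p-values are
Benjamini–Hochberg adjusted within each drug's family of tested terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

_LN2 = math.log(2.0)

# Bate-1998 prior: Beta(1, ·) margins, joint prior tied so that the prior
# expectation of IC is 0
_A1 = 1.0  # alpha1, prior a+b
_B1 = 1.0  # beta1, prior a+c
_AL = 2.0  # alpha
_BE = 2.0  # beta
_G11 = 1.0  # gamma11


@dataclass(frozen=True)
class ContingencyTable:
    """Four-fold report counts for one (drug, PT) pair."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalRules:
    """Signal-calling thresholds.

    ``ror_positive``:  a ≥ min_count and ROR CI lower bound > 1.
    ``prr_positive``:  PRR ≥ 2, χ² ≥ 4 and a ≥ min_count.
    ``bcpnn_positive``: IC025 > 0 and BH-adjusted p < alpha.
    ``suspicious`` = ROR-positive ∧ PRR-positive;
    ``positive_signal`` = BCPNN-positive.
    """

    min_count: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    alpha: float = 0.05
    bh_family: str = "per_drug"  # or "global"


# ---------------------------------------------------------------------------
# contingency construction
# ---------------------------------------------------------------------------


def build_contingency(
    cohort_cases: pd.DataFrame,
    events: pd.DataFrame,
    background_cases: pd.DataFrame,
    drug: str,
    pt: str,
) -> ContingencyTable:
    """Four-fold table for one pair against the background comparator."""
    drug_ids = cohort_cases.loc[cohort_cases["drug"] == drug, "primaryid"]
    bg_ids = background_cases["primaryid"]
    with_pt = set(events.loc[events["pt"] == pt, "primaryid"])
    a = int(drug_ids.isin(with_pt).sum())
    b = int(len(drug_ids) - a)
    c = int(bg_ids.isin(with_pt).sum())
    d = int(len(bg_ids) - c)
    return ContingencyTable(a, b, c, d)


def contingency_tables(
    cohort_cases: pd.DataFrame,
    events: pd.DataFrame,
    background_cases: pd.DataFrame,
    pts: list[str] | None = None,
    combined_label: str | None = "CDK4/6 inhibitors",
) -> pd.DataFrame:
    """All (drug, PT) four-fold tables, vectorized.

    ``cohort_cases`` must carry ``primaryid`` and the assigned ``drug``;
    ``events`` one row per (report, PT); ``background_cases`` the
    comparator reports.  When ``combined_label`` is set, a pseudo-drug
    aggregating the whole cohort is appended.  Returns a frame with
    columns ``drug, pt, a, b, c, d``.
    """
    ev = events.drop_duplicates(["primaryid", "pt"])
    if pts is None:
        pts = sorted(ev["pt"].unique())
    pt_index = pd.Index(pts, name="pt")

    cohort_ev = ev.merge(
        cohort_cases[["primaryid", "drug"]], on="primaryid", how="inner"
    )
    bg_ev = ev[ev["primaryid"].isin(background_cases["primaryid"])]

    n_bg = len(background_cases)
    c_counts = (
        bg_ev.groupby("pt")["primaryid"].nunique().reindex(pt_index, fill_value=0)
    )

    rows = []
    drug_sizes = cohort_cases.groupby("drug")["primaryid"].nunique()
    a_counts = (
        cohort_ev.groupby(["drug", "pt"])["primaryid"].nunique().unstack(fill_value=0)
    )
    drug_list = list(drug_sizes.index)
    for drug in drug_list:
        n_drug = int(drug_sizes[drug])
        a_row = (
            a_counts.loc[drug].reindex(pt_index, fill_value=0)
            if drug in a_counts.index
            else pd.Series(0, index=pt_index)
        )
        for pt in pts:
            a = int(a_row[pt])
            rows.append((drug, pt, a, n_drug - a, int(c_counts[pt]), n_bg - int(c_counts[pt])))
    if combined_label is not None:
        n_all = cohort_cases["primaryid"].nunique()
        a_all = (
            cohort_ev.groupby("pt")["primaryid"].nunique().reindex(pt_index, fill_value=0)
        )
        for pt in pts:
            a = int(a_all[pt])
            rows.append(
                (combined_label, pt, a, n_all - a, int(c_counts[pt]), n_bg - int(c_counts[pt]))
            )
    return pd.DataFrame(rows, columns=["drug", "pt", "a", "b", "c", "d"])


# ---------------------------------------------------------------------------
# statistics (vectorized over numpy arrays; scalars broadcast)
# ---------------------------------------------------------------------------


def _continuity(a, b, c, d):
    """Haldane–Anscombe 0.5 correction where any cell is zero (and a > 0)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) & (a > 0)
    add = np.where(zero, 0.5, 0.0)
    return a + add, b + add, c + add, d + add, zero


def ror(a, b, c, d, alpha: float = 0.05):
    """Reporting odds ratio with Woolf CI.

    Returns ``(ror, ci_low, ci_high)``; NaN (undefined marker) where
    ``a == 0`` or a margin is empty.
    """
    a0 = np.asarray(a, dtype=float)
    ac, bc_, cc, dc, _ = _continuity(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (ac * dc) / (bc_ * cc)
        se = np.sqrt(1 / ac + 1 / bc_ + 1 / cc + 1 / dc)
        z = stats.norm.ppf(1 - alpha / 2)
        lo = est * np.exp(-z * se)
        hi = est * np.exp(z * se)
    undef = (a0 == 0) | ~np.isfinite(est)
    est = np.where(undef, np.nan, est)
    lo = np.where(undef, np.nan, lo)
    hi = np.where(undef, np.nan, hi)
    if np.ndim(a) == 0:
        return float(est), float(lo), float(hi)
    return est, lo, hi


def prr(a, b, c, d, yates: bool = True):
    """Proportional reporting ratio with the 1-df χ² test.

    Returns ``(prr, chi2, p_value)``; PRR is NaN where a row margin is
    empty or ``a == 0``; the χ² uses the raw counts (Yates-corrected by
    default).
    """
    a0, b0, c0, d0 = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    ac, bc_, cc, dc, _ = _continuity(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (ac / (ac + bc_)) / (cc / (cc + dc))
        n = a0 + b0 + c0 + d0
        num = np.abs(a0 * d0 - b0 * c0)
        if yates:
            num = np.maximum(num - n / 2, 0.0)
        denom = (a0 + b0) * (c0 + d0) * (a0 + c0) * (b0 + d0)
        chi2 = np.where(denom > 0, n * num**2 / denom, np.nan)
        p = stats.chi2.sf(chi2, df=1)
    undef = (a0 == 0) | (a0 + b0 == 0) | (c0 + d0 == 0)
    est = np.where(undef, np.nan, est)
    if np.ndim(a) == 0:
        return float(est), float(chi2), float(p)
    return est, chi2, p


def _bcpnn_priors(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    n1_ = a + b  # drug margin
    n_1 = a + c  # event margin
    gamma = _G11 * (n + _AL) * (n + _BE) / ((n1_ + _A1) * (n_1 + _B1))
    return n, n1_, n_1, gamma


def bcpnn_ic(
    a,
    b,
    c,
    d,
    method: str = "closed_form",
    n_draws: int = 10_000,
    seed: int | None = None,
    q: float = 0.025,
):
    """BCPNN information component.

    ``closed_form`` returns ``(E[IC], E[IC] − 1.96·√V[IC])``;
    ``monte_carlo`` samples the posterior (independent Beta margins and
    joint cell, mirroring the closed form's moment structure) and returns
    the posterior mean and the ``q`` quantile.
    """
    if method not in {"closed_form", "monte_carlo"}:
        raise ConfigurationError(f"unknown BCPNN method {method!r}")
    n, n1_, n_1, gamma = _bcpnn_priors(a, b, c, d)
    av = np.asarray(a, dtype=float)
    if method == "closed_form":
        e_ic = (
            np.log((av + _G11) * (n + _AL) * (n + _BE))
            - np.log((n + gamma) * (n1_ + _A1) * (n_1 + _B1))
        ) / _LN2
        v_ic = (
            (n - av + gamma - _G11) / ((av + _G11) * (1 + n + gamma))
            + (n - n1_ + _AL - _A1) / ((n1_ + _A1) * (1 + n + _AL))
            + (n - n_1 + _BE - _B1) / ((n_1 + _B1) * (1 + n + _BE))
        ) / _LN2**2
        ic = e_ic
        ic025 = e_ic - 1.96 * np.sqrt(v_ic)
    else:
        if n_draws < 100:
            raise ConfigurationError("monte_carlo requires n_draws >= 100")
        rng = np.random.default_rng(seed)
        draws = _ic_posterior_draws(av, n, n1_, n_1, gamma, rng, n_draws)
        ic = draws.mean(axis=-1)
        ic025 = np.quantile(draws, q, axis=-1)
    if np.ndim(a) == 0:
        return float(ic), float(ic025)
    return ic, ic025


def _ic_posterior_draws(av, n, n1_, n_1, gamma, rng, n_draws):
    shape = np.broadcast_shapes(np.shape(av), np.shape(n))
    av, n, n1_, n_1, gamma = (
        np.broadcast_to(x, shape) for x in (av, n, n1_, n_1, gamma)
    )
    size = shape + (n_draws,)
    p11 = rng.beta((av + _G11)[..., None], (n - av + gamma - _G11)[..., None], size)
    p1_ = rng.beta((n1_ + _A1)[..., None], (n - n1_ + _AL - _A1)[..., None], size)
    p_1 = rng.beta((n_1 + _B1)[..., None], (n - n_1 + _BE - _B1)[..., None], size)
    return np.log(p11 / (p1_ * p_1)) / _LN2


def ic_posterior_interval(a, b, c, d, n_draws=100_000, seed=None, level=0.99):
    """Monte-Carlo equal-tailed posterior interval for IC (cross-checks)."""
    n, n1_, n_1, gamma = _bcpnn_priors(a, b, c, d)
    rng = np.random.default_rng(seed)
    draws = _ic_posterior_draws(
        np.asarray(a, float), n, n1_, n_1, gamma, rng, n_draws
    )
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2], axis=-1)
    return lo, hi


# ---------------------------------------------------------------------------
# signal calling
# ---------------------------------------------------------------------------


def disproportionality(
    tables: pd.DataFrame,
    rules: SignalRules = SignalRules(),
    ic_method: str = "closed_form",
    ic_draws: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All statistics plus signal flags for a frame of four-fold tables.

    ``tables`` needs columns ``drug, pt, a, b, c, d`` (as from
    :func:`contingency_tables`).
    """
    out = tables.copy().reset_index(drop=True)
    a, b, c, d = (out[k].to_numpy(float) for k in ("a", "b", "c", "d"))
    out["n"] = out["a"]
    est, lo, hi = ror(a, b, c, d, alpha=rules.alpha)
    out["ror"], out["ror_low"], out["ror_high"] = est, lo, hi
    p_est, chi2, p = prr(a, b, c, d)
    out["prr"], out["prr_chi2"], out["p_value"] = p_est, chi2, p
    ic, ic025 = bcpnn_ic(a, b, c, d, method=ic_method, n_draws=ic_draws, seed=seed)
    out["ic"], out["ic025"] = ic, ic025
    zero = np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0
    out["continuity_corrected"] = zero & (a > 0)
    return call_signals(out, rules)


def call_signals(results: pd.DataFrame, rules: SignalRules = SignalRules()) -> pd.DataFrame:
    """Apply BH adjustment and the signal-classification thresholds."""
    out = results.copy()
    out["p_adjusted"] = np.nan
    groups = [out.index] if rules.bh_family == "global" else [
        idx for _, idx in out.groupby("drug").groups.items()
    ]
    for idx in groups:
        p = out.loc[idx, "p_value"].to_numpy(float)
        ok = np.isfinite(p)
        if ok.sum():
            adj = np.full(len(p), np.nan)
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            out.loc[idx, "p_adjusted"] = adj

    n = out["a"].to_numpy(float)
    out["ror_positive"] = (
        (n >= rules.min_count) & (out["ror_low"] > rules.ror_ci_low)
    ).fillna(False)
    out["prr_positive"] = (
        (n >= rules.min_count)
        & (out["prr"] >= rules.prr_min)
        & (out["prr_chi2"] >= rules.chi2_min)
    ).fillna(False)
    out["bcpnn_positive"] = (
        (out["ic025"] > rules.ic025_min) & (out["p_adjusted"] < rules.alpha)
    ).fillna(False)
    out["suspicious"] = out["ror_positive"] & out["prr_positive"]
    out["positive_signal"] = out["bcpnn_positive"]
    return out
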