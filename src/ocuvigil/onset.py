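"""Time-to-onset and severity summaries.

Time to onset (TTO) is the delay in days between the first full-precision
therapy start date of the suspect drug on a report and the event date.
Partial or missing dates censor the record; negative differences are
excluded and counted.  Quantiles use linear interpolation throughout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import dates


def compute_tto(
    cohort_cases: pd.DataFrame,
    exposures: pd.DataFrame,
    events: pd.DataFrame,
    target_generics: Sequence[str],
) -> pd.DataFrame:
    """One onset record per (cohort report, PT).

    Columns: ``primaryid, drug, pt, tto_days, censored``.  ``tto_days`` is
    present only when both the earliest target-drug start date and the
    event date are full precision and the difference is non-negative.
    """
    cases = cohort_cases.copy()
    tgt = exposures[
        exposures["generic_name"].isin(list(target_generics))
        & (exposures["start_precision"] == dates.PRECISION_DAY)
    ]
    first_start = tgt.groupby("primaryid")["start_date"].min()
    cases["start_date"] = cases["primaryid"].map(first_start)

    event_ok = cases["event_precision"] == dates.PRECISION_DAY
    tto = (cases["event_date"] - cases["start_date"]).dt.days.astype(float)
    tto = tto.where(event_ok & cases["start_date"].notna())
    negative = tto < 0
    cases["tto_days"] = tto.where(~negative)
    cases["censored"] = cases["tto_days"].isna()

    rec = events.merge(
        cases[["primaryid", "drug", "tto_days", "censored"]],
        on="primaryid",
        how="inner",
    )
    rec.attrs["n_negative_excluded"] = int(negative.sum())
    return rec[["primaryid", "drug", "pt", "tto_days", "censored"]]


def summarize_tto(
    records: pd.DataFrame,
    group_by: str | list[str] = "drug",
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-group median / Q1 / Q3 / n / missing fraction of onset days."""
    keys = [group_by] if isinstance(group_by, str) else list(group_by)

    def _one(g: pd.DataFrame) -> pd.Series:
        vals = g["tto_days"].dropna().to_numpy()
        n = len(vals)
        if n:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        return pd.Series(
            {
                "n": n,
                "median": med,
                "q1": q1,
                "q3": q3,
                "missing_fraction": g["tto_days"].isna().mean(),
                "below_min_n": n < min_n,
            }
        )

    if records.empty:
        return pd.DataFrame(
            columns=keys + ["n", "median", "q1", "q3", "missing_fraction", "below_min_n"]
        )
    out = records.groupby(keys, dropna=False).apply(_one, include_groups=False)
    out["n"] = out["n"].astype(int)
    out["below_min_n"] = out["below_min_n"].astype(bool)
    return out.reset_index()


def severity_pyramid(
    cohort_cases: pd.DataFrame, events: pd.DataFrame, top_k: int = 20
) -> pd.DataFrame:
    """Report counts with serious% and death% for the top-k PTs.

    Percentages are over reports with a known outcome; death counts inside
    serious.  Denominators are exported so the choice is auditable.
    """
    ev = events.drop_duplicates(["primaryid", "pt"]).merge(
        cohort_cases[["primaryid", "outcome_class"]], on="primaryid", how="inner"
    )
    counts = ev.groupby("pt")["primaryid"].nunique().sort_values(ascending=False)
    top = counts.head(top_k).index

    rows = []
    for pt in top:
        sub = ev[ev["pt"] == pt]
        known = sub[sub["outcome_class"] != "missing"]
        denom = len(known)
        n_death = int((known["outcome_class"] == "death").sum())
        n_serious = int((known["outcome_class"] == "serious").sum()) + n_death
        rows.append(
            {
                "pt": pt,
                "n_reports": int(counts[pt]),
                "n_known_outcome": denom,
                "serious_pct": 100 * n_serious / denom if denom else np.nan,
                "death_pct": 100 * n_death / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pt", "n_reports", "n_known_outcome", "serious_pct", "death_pct"],
    )
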