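"""Duplicate-report detection and resolution.

Two reports are linked as duplicates only when *all* core fields match —
identical first-10-character caseid prefix, identical Preferred Term set,
and therapy start dates (both full precision) no more than 7 days apart —
*and* all auxiliary fields match: same sex, age gap ≤ 5 years, same
reporting country.  A comparison in which a required field is missing on
either side never links (conservative: missingness is not evidence of
identity).  Duplicate clusters are connected components of the link
relation; one report per cluster is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import dates
from .errors import ConfigurationError


@dataclass(frozen=True)
class DuplicateRule:
    """Matching tolerances for the dual core + auxiliary criterion."""

    caseid_prefix_len: int = 10
    max_start_date_gap_days: int = 7
    max_age_gap_years: float = 5
    require_same_sex: bool = True
    require_same_country: bool = True
    require_same_pt: bool = True

    def __post_init__(self) -> None:
        if self.caseid_prefix_len < 1:
            raise ConfigurationError("caseid_prefix_len must be >= 1")
        if self.max_start_date_gap_days < 0 or self.max_age_gap_years < 0:
            raise ConfigurationError("matching gaps must be >= 0")


def report_signatures(
    cases: pd.DataFrame, exposures: pd.DataFrame, events: pd.DataFrame
) -> pd.DataFrame:
    """Per-report comparison key: caseid prefix source, PT set, earliest
    full-precision start date (as ordinal days), sex, age, country."""
    sig = cases.set_index("primaryid")[
        ["caseid", "sex", "age_years", "country"]
    ].copy()

    pt_key = (
        events.assign(pt_norm=events["pt"].str.strip().str.upper())
        .sort_values("pt_norm", kind="stable")
        .groupby("primaryid")["pt_norm"]
        .agg("|".join)
    )
    sig["pt_key"] = sig.index.map(pt_key)

    full = exposures[exposures["start_precision"] == dates.PRECISION_DAY]
    if len(full):
        start = full.groupby("primaryid")["start_date"].min()
        start_days = (
            (start - pd.Timestamp("1970-01-01")).dt.days.astype(float)
        )
    else:
        start_days = pd.Series(dtype=float)
    sig["start_days"] = sig.index.map(start_days)
    return sig


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = p = self.parent.setdefault(p, p)
            x = p
            p = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _pair_links(sig: pd.DataFrame, rule: DuplicateRule) -> list[tuple[str, str]]:
    """All linked report pairs; blocked on the caseid prefix for speed."""
    sig = sig.copy()
    sig["prefix"] = sig["caseid"].astype(str).str[: rule.caseid_prefix_len]
    sig = sig[sig["prefix"].duplicated(keep=False)]
    links: list[tuple[str, str]] = []
    for _, block in sig.groupby("prefix", sort=True):
        if len(block) < 2:
            continue
        ids = block.index.to_numpy()
        for i, j in combinations(range(len(ids)), 2):
            a, b = block.iloc[i], block.iloc[j]
            if _match(a, b, rule):
                links.append((ids[i], ids[j]))
    return links


def _match(a: pd.Series, b: pd.Series, rule: DuplicateRule) -> bool:
    # core: PT set (exact, non-empty on both sides)
    if rule.require_same_pt:
        if not isinstance(a["pt_key"], str) or not isinstance(b["pt_key"], str):
            return False
        if a["pt_key"] == "" or a["pt_key"] != b["pt_key"]:
            return False
    # core: start-date gap, both full precision
    if np.isnan(a["start_days"]) or np.isnan(b["start_days"]):
        return False
    if abs(a["start_days"] - b["start_days"]) > rule.max_start_date_gap_days:
        return False
    # auxiliary: sex, age, country — missing never links
    if rule.require_same_sex:
        if a["sex"] in ("", None) or a["sex"] != b["sex"]:
            return False
    if np.isnan(a["age_years"]) or np.isnan(b["age_years"]):
        return False
    if abs(a["age_years"] - b["age_years"]) > rule.max_age_gap_years:
        return False
    if rule.require_same_country:
        if a["country"] in ("", None) or a["country"] != b["country"]:
            return False
    return True


def find_duplicates(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    events: pd.DataFrame,
    rule: DuplicateRule = DuplicateRule(),
) -> list[list[str]]:
    """Duplicate clusters (size ≥ 2) as sorted lists of report keys.

    Clustering is order-invariant: the result is sorted by each cluster's
    smallest key.
    """
    if cases.empty:
        return []
    sig = report_signatures(cases, exposures, events)
    links = _pair_links(sig, rule)
    uf = _UnionFind()
    for a, b in links:
        uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for key in uf.parent:
        groups.setdefault(uf.find(key), []).append(key)
    clusters = [sorted(v) for v in groups.values() if len(v) >= 2]
    return sorted(clusters, key=lambda c: c[0])


def resolve_duplicates(
    clusters: list[list[str]],
    cases: pd.DataFrame,
    policy: str = "keep_latest",
) -> tuple[set[str], pd.DataFrame]:
    """Choose one report per cluster; return removed keys and a removal log.

    The default policy keeps the report with the most recent FDA receipt
    date, ties broken by the largest primaryid.
    """
    if policy != "keep_latest":
        raise ConfigurationError(f"unknown duplicate-resolution policy {policy!r}")
    fda = cases.set_index("primaryid")["fda_date"]
    removed: set[str] = set()
    rows = []
    for cluster_id, cluster in enumerate(clusters):
        def sort_key(pid: str):
            d = fda.get(pid, pd.NaT)
            ts = d.value if pd.notna(d) else -(2**62)
            num = int(pid) if str(pid).isdigit() else 0
            return (ts, num, str(pid))

        ordered = sorted(cluster, key=sort_key)
        keep = ordered[-1]
        drop = ordered[:-1]
        removed.update(drop)
        rows.append(
            {
                "cluster_id": cluster_id,
                "retained": keep,
                "removed": ";".join(drop),
                "cluster_size": len(cluster),
            }
        )
    log = pd.DataFrame(
        rows, columns=["cluster_id", "retained", "removed", "cluster_size"]
    )
    return removed, log


def drop_duplicates(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    events: pd.DataFrame,
    rule: DuplicateRule = DuplicateRule(),
    policy: str = "keep_latest",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Find, resolve and drop duplicates across the linked tables."""
    clusters = find_duplicates(cases, exposures, events, rule)
    removed, log = resolve_duplicates(clusters, cases, policy)
    keep = ~cases["primaryid"].isin(removed)
    cases = cases[keep]
    exposures = exposures[exposures["primaryid"].isin(cases["primaryid"])]
    events = events[events["primaryid"].isin(cases["primaryid"])]
    return cases, exposures, events, log
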