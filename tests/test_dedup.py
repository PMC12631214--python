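"""Duplicate matching: tolerance edges, brute-force oracle, resolution."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import ocuvigil as ov
from ocuvigil import dedup, io_faers
from ocuvigil.dedup import DuplicateRule
from ocuvigil.errors import ConfigurationError

from conftest import make_case, make_exposure


def _frames(case_rows, exp_rows, event_rows):
    cases = pd.DataFrame(case_rows)
    exposures = pd.DataFrame(exp_rows)
    events = pd.DataFrame(event_rows)
    return cases, exposures, events


def _pair(start_gap_days=0, age_gap=0, sex2="F", country2="US", pt2="Dry eye",
          prefix2=None, precision2="day"):
    c1 = make_case(primaryid="10000000011", caseid="1000000001")
    c2 = make_case(
        primaryid="10000000012",
        caseid=(prefix2 or "1000000001") + "X" if prefix2 else "1000000001",
        sex=sex2,
        age_years=60.0 + age_gap,
        country=country2,
    )
    e1 = make_exposure("10000000011", "2020-03-01")
    e2 = make_exposure(
        "10000000012",
        pd.Timestamp("2020-03-01") + pd.Timedelta(days=start_gap_days),
        precision=precision2,
    )
    ev = [
        {"primaryid": "10000000011", "pt": "Dry eye"},
        {"primaryid": "10000000012", "pt": pt2},
    ]
    return _frames([c1, c2], [e1, e2], ev)


def n_clusters(cases, exposures, events, rule=DuplicateRule()):
    return len(dedup.find_duplicates(cases, exposures, events, rule))


@pytest.mark.parametrize(
    "kwargs, linked",
    [
        ({"start_gap_days": 5}, True),   # within the 7-day window
        ({"start_gap_days": 7}, True),
        ({"start_gap_days": 8}, False),
        ({"age_gap": 5}, True),          # within the 5-year window
        ({"age_gap": 6}, False),
        ({"sex2": "M"}, False),
        ({"country2": "DE"}, False),
        ({"pt2": "Cataract"}, False),
        ({"sex2": ""}, False),           # missing field never links
        ({"precision2": "month"}, False),  # partial start date never links
    ],
)
def test_dual_matching_tolerances(kwargs, linked):
    cases, exposures, events = _pair(**kwargs)
    assert n_clusters(cases, exposures, events) == (1 if linked else 0)


def test_single_report_no_clusters():
    cases, exposures, events = _frames(
        [make_case()], [make_exposure("100000000011", "2020-01-01")],
        [{"primaryid": "100000000011", "pt": "Dry eye"}],
    )
    assert dedup.find_duplicates(cases, exposures, events) == []


def test_pt_set_must_match_as_a_whole():
    cases, exposures, events = _pair()
    events = pd.concat(
        [events, pd.DataFrame([{"primaryid": "10000000011", "pt": "Cataract"}])],
        ignore_index=True,
    )
    assert n_clusters(cases, exposures, events) == 0


# -- brute-force oracle ------------------------------------------------------


def brute_force_pairs(cases, exposures, events, rule=DuplicateRule()):
    """Independent O(n²) matcher over all report pairs."""
    pts = {}
    for pid, grp in events.groupby("primaryid"):
        pts[pid] = tuple(sorted(grp["pt"].str.upper()))
    starts = {}
    full = exposures[exposures["start_precision"] == "day"]
    for pid, grp in full.groupby("primaryid"):
        starts[pid] = grp["start_date"].min()
    rows = cases.set_index("primaryid").to_dict("index")
    pairs = set()
    for a, b in combinations(list(rows), 2):
        ra, rb = rows[a], rows[b]
        if str(ra["caseid"])[:rule.caseid_prefix_len] != str(rb["caseid"])[:rule.caseid_prefix_len]:
            continue
        if pts.get(a, ()) == () or pts.get(a) != pts.get(b):
            continue
        if a not in starts or b not in starts:
            continue
        if abs((starts[a] - starts[b]).days) > rule.max_start_date_gap_days:
            continue
        if ra["sex"] in ("", None) or ra["sex"] != rb["sex"]:
            continue
        if pd.isna(ra["age_years"]) or pd.isna(rb["age_years"]):
            continue
        if abs(ra["age_years"] - rb["age_years"]) > rule.max_age_gap_years:
            continue
        if ra["country"] in ("", None) or ra["country"] != rb["country"]:
            continue
        pairs.add(frozenset((a, b)))
    return pairs


def _clusters_from_pairs(pairs):
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(tuple(p) for p in pairs)
    return sorted(sorted(c) for c in nx.connected_components(g))


def _synth_linked_frames(n=400, seed=13, duplicate_rate=0.1):
    cfg = ov.default_config(n_reports=n, seed=seed, duplicate_rate=duplicate_rate)
    db = ov.generate_database(cfg)
    raw = io_faers.RawTables(**{k.lower(): v for k, v in db.tables.items()})
    cases = io_faers.build_case_table(raw)
    exposures, _ = io_faers.build_exposures(raw, io_faers.default_name_table())
    events = raw.reac[["primaryid", "pt"]]
    return db, cases, exposures, events


def test_clusters_equal_brute_force_on_synth_database():
    db, cases, exposures, events = _synth_linked_frames()
    got = dedup.find_duplicates(cases, exposures, events)
    expected = _clusters_from_pairs(brute_force_pairs(cases, exposures, events))
    assert sorted(got) == expected


def test_injected_duplicate_recall_is_total():
    db, cases, exposures, events = _synth_linked_frames()
    clusters = dedup.find_duplicates(cases, exposures, events)
    member = {}
    for i, cluster in enumerate(clusters):
        for pid in cluster:
            member[pid] = i
    for orig, clone in zip(
        db.duplicate_log["original_primaryid"], db.duplicate_log["duplicate_primaryid"]
    ):
        assert member.get(orig) is not None and member.get(orig) == member.get(clone)


def test_loosening_tolerances_never_drops_links():
    _, cases, exposures, events = _synth_linked_frames(n=300, seed=29)
    strict = brute_force_pairs(cases, exposures, events, DuplicateRule())
    loose_days = brute_force_pairs(
        cases, exposures, events, DuplicateRule(max_start_date_gap_days=14)
    )
    loose_age = brute_force_pairs(
        cases, exposures, events, DuplicateRule(max_age_gap_years=10)
    )
    assert strict <= loose_days
    assert strict <= loose_age
    # the production matcher agrees under the loosened rules too
    got = dedup.find_duplicates(
        cases, exposures, events, DuplicateRule(max_start_date_gap_days=14)
    )
    assert sorted(got) == _clusters_from_pairs(loose_days)


def test_clustering_is_permutation_invariant():
    _, cases, exposures, events = _synth_linked_frames(n=200, seed=31)
    base = dedup.find_duplicates(cases, exposures, events)
    rng = np.random.default_rng(0)
    shuffled = cases.sample(frac=1, random_state=rng.integers(2**31)).reset_index(drop=True)
    assert dedup.find_duplicates(shuffled, exposures, events) == base


# -- resolution --------------------------------------------------------------


def test_resolution_keeps_latest_receipt():
    rows = [
        make_case(primaryid="1", fda_date="2020-01-01"),
        make_case(primaryid="2", fda_date="2021-01-01"),
        make_case(primaryid="3", fda_date="2020-06-01"),
    ]
    cases = pd.DataFrame(rows)
    removed, log = dedup.resolve_duplicates([["1", "2", "3"]], cases)
    assert removed == {"1", "3"}
    assert log.iloc[0]["retained"] == "2"
    assert log.iloc[0]["cluster_size"] == 3


def test_resolution_tie_break_on_primaryid():
    rows = [
        make_case(primaryid="17", fda_date="2020-01-01"),
        make_case(primaryid="9", fda_date="2020-01-01"),
    ]
    removed, _ = dedup.resolve_duplicates([["17", "9"]], pd.DataFrame(rows))
    assert removed == {"9"}


def test_no_clusters_leaves_input_unchanged():
    cases = pd.DataFrame([make_case(primaryid="1")])
    removed, log = dedup.resolve_duplicates([], cases)
    assert removed == set() and len(log) == 0


def test_unknown_policy_is_error():
    with pytest.raises(ConfigurationError, match="policy"):
        dedup.resolve_duplicates([], pd.DataFrame([make_case()]), policy="random")


def test_invalid_rule_rejected():
    with pytest.raises(ConfigurationError):
        DuplicateRule(caseid_prefix_len=0)
    with pytest.raises(ConfigurationError):
        DuplicateRule(max_start_date_gap_days=-1)
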