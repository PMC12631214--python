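"""Disproportionality statistics against hand arithmetic and independent
oracles, plus signal-classification thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ocuvigil as ov
from ocuvigil import signals
from ocuvigil.errors import ConfigurationError


def random_tables(n, seed, low=0, high=2000):
    rng = np.random.default_rng(seed)
    t = rng.integers(low, high, size=(n, 4))
    return t[:, 0], t[:, 1], t[:, 2], t[:, 3]


# -- ROR ---------------------------------------------------------------------


def test_ror_hand_example():
    est, lo, hi = signals.ror(10, 90, 100, 9900)
    assert est == pytest.approx(11.0)
    se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
    assert lo == pytest.approx(11.0 * math.exp(-1.959963984540054 * se))
    assert hi == pytest.approx(11.0 * math.exp(1.959963984540054 * se))


def test_ror_symmetric_table_centred_on_one():
    est, lo, hi = signals.ror(5, 5, 5, 5)
    assert est == pytest.approx(1.0)
    assert lo * hi == pytest.approx(1.0)  # symmetric about 1 in log scale


def test_ror_undefined_when_a_zero():
    est, lo, hi = signals.ror(0, 100, 50, 9000)
    assert np.isnan(est) and np.isnan(lo) and np.isnan(hi)


def test_ror_swap_symmetry():
    a, b, c, d = random_tables(200, 3, low=1)
    est, _, _ = signals.ror(a, b, c, d)
    inv, _, _ = signals.ror(c, d, a, b)
    np.testing.assert_allclose(est * inv, 1.0, rtol=1e-9)


def test_ror_strictly_increasing_in_a():
    rors = [signals.ror(a, 50, 30, 900)[0] for a in range(1, 30)]
    assert all(x < y for x, y in zip(rors, rors[1:]))


# -- PRR ---------------------------------------------------------------------


def test_prr_hand_example():
    est, chi2, p = signals.prr(10, 90, 100, 9900)
    assert est == pytest.approx(10.0)
    assert p == pytest.approx(stats.chi2.sf(chi2, 1))


def test_prr_independence_gives_one():
    est, chi2, _ = signals.prr(10, 90, 100, 900)
    assert est == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-6)


def test_prr_strictly_increasing_in_a():
    prrs = [signals.prr(a, 50, 30, 900)[0] for a in range(1, 30)]
    assert all(x < y for x, y in zip(prrs, prrs[1:]))


def test_chi2_matches_scipy_contingency_oracle():
    a, b, c, d = random_tables(200, 7, low=1)
    _, chi2, p = signals.prr(a, b, c, d)
    for i in range(200):
        ref = stats.chi2_contingency(
            [[a[i], b[i]], [c[i], d[i]]], correction=True
        )
        assert chi2[i] == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
        assert p[i] == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


def test_vectorized_equals_scalar_on_1000_random_tables():
    a, b, c, d = random_tables(1000, 11)
    v_ror = signals.ror(a, b, c, d)
    v_prr = signals.prr(a, b, c, d)
    v_ic = signals.bcpnn_ic(a, b, c, d)
    for i in range(1000):
        s_ror = signals.ror(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        s_prr = signals.prr(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        s_ic = signals.bcpnn_ic(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        for vec, scal in zip(v_ror + v_prr + v_ic, s_ror + s_prr + s_ic):
            vi = vec[i]
            assert (np.isnan(vi) and np.isnan(scal)) or vi == pytest.approx(
                scal, rel=1e-9, abs=1e-12
            )


# -- BCPNN -------------------------------------------------------------------


def test_ic_near_zero_under_independence():
    # a equals its expectation under independence; all counts large
    ic, _ = signals.bcpnn_ic(1000, 99000, 9900, 980100)
    assert abs(ic) < 0.05


def test_ic025_below_ic_everywhere():
    a, b, c, d = random_tables(300, 17)
    ic, ic025 = signals.bcpnn_ic(a, b, c, d)
    assert (ic025 < ic).all()


def test_ic_approaches_log2_rate_ratio_at_scale():
    a, b, c, d = 30, 970, 10, 990
    for k in (1, 10, 100, 1000):
        ic, _ = signals.bcpnn_ic(a * k, b * k, c * k, d * k)
    n = (a + b + c + d) * 1000
    expected = math.log2((a * 1000 * n) / ((a + b) * 1000 * (a + c) * 1000))
    assert ic == pytest.approx(expected, abs=0.01)


def test_closed_form_ic_inside_monte_carlo_interval():
    a, b, c, d = random_tables(50, 23, low=1, high=500)
    ic, _ = signals.bcpnn_ic(a, b, c, d)
    lo, hi = signals.ic_posterior_interval(a, b, c, d, n_draws=100_000, seed=5)
    assert ((ic > lo) & (ic < hi)).all()


def test_monte_carlo_ic_close_to_closed_form():
    ic_cf, ic025_cf = signals.bcpnn_ic(40, 960, 200, 9800)
    ic_mc, ic025_mc = signals.bcpnn_ic(
        40, 960, 200, 9800, method="monte_carlo", n_draws=200_000, seed=1
    )
    assert ic_mc == pytest.approx(ic_cf, abs=0.05)
    assert ic025_mc == pytest.approx(ic025_cf, abs=0.1)


def test_monte_carlo_draw_floor():
    with pytest.raises(ConfigurationError, match="n_draws"):
        signals.bcpnn_ic(5, 5, 5, 5, method="monte_carlo", n_draws=10)


# -- contingency construction ------------------------------------------------


def test_contingency_direct_counting():
    cohort = pd.DataFrame(
        {"primaryid": [str(i) for i in range(100)], "drug": ["DrugA"] * 100}
    )
    background = pd.DataFrame({"primaryid": [f"b{i}" for i in range(10000)]})
    events = pd.DataFrame(
        {
            "primaryid": [str(i) for i in range(10)]
            + [f"b{i}" for i in range(100)],
            "pt": ["PT X"] * 110,
        }
    )
    table = signals.build_contingency(cohort, events, background, "DrugA", "PT X")
    assert table.as_tuple() == (10, 90, 100, 9900)
    absent = signals.build_contingency(cohort, events, background, "DrugA", "PT Z")
    assert absent.a == 0 and absent.c == 0


def test_contingency_tables_match_bruteforce_recount(pipeline_state):
    state = pipeline_state
    cohort = state.cohort.cohort_cases
    bg = state.cohort.background_cases
    results = state.signal_results
    rng = np.random.default_rng(2)
    sample = results.sample(12, random_state=int(rng.integers(2**31)))
    for _, row in sample.iterrows():
        if row["drug"] == "CDK4/6 inhibitors":
            ids = set(cohort["primaryid"])
        else:
            ids = set(cohort.loc[cohort["drug"] == row["drug"], "primaryid"])
        with_pt = set(state.events.loc[state.events["pt"] == row["pt"], "primaryid"])
        bg_ids = set(bg["primaryid"])
        assert row["a"] == len(ids & with_pt)
        assert row["b"] == len(ids - with_pt)
        assert row["c"] == len(bg_ids & with_pt)
        assert row["d"] == len(bg_ids - with_pt)


# -- signal calling ----------------------------------------------------------


def _results_frame(rows):
    frame = pd.DataFrame(rows)
    for col, default in (
        ("b", 1000), ("c", 100), ("d", 10000), ("prr", 1.0),
        ("prr_chi2", 0.0), ("p_value", 0.5), ("ic", 0.0), ("ic025", -1.0),
    ):
        if col not in frame.columns:
            frame[col] = default
    return frame


def test_printed_ror_rows_classify_positive():
    # rows with the published point estimates: Cataract 239 2.00 (1.69–2.37),
    # Blindness 122 2.14 (1.69–2.73)
    frame = _results_frame(
        [
            {"drug": "CDK4/6 inhibitors", "pt": "Cataract", "a": 239,
             "ror": 2.00, "ror_low": 1.69, "ror_high": 2.37},
            {"drug": "CDK4/6 inhibitors", "pt": "Blindness", "a": 122,
             "ror": 2.14, "ror_low": 1.69, "ror_high": 2.73},
        ]
    )
    out = signals.call_signals(frame)
    assert out["ror_positive"].all()


def test_minimum_count_rule_blocks_tiny_cells():
    frame = _results_frame(
        [{"drug": "D", "pt": "P", "a": 2, "ror": 50.0, "ror_low": 5.0,
          "ror_high": 500.0, "prr": 50.0, "prr_chi2": 30.0}]
    )
    out = signals.call_signals(frame)
    assert not out["ror_positive"].any()
    assert not out["prr_positive"].any()


def test_bh_adjustment_is_per_drug_and_monotone():
    rng = np.random.default_rng(5)
    rows = []
    for drug in ("D1", "D2"):
        for i in range(20):
            rows.append(
                {"drug": drug, "pt": f"P{i}", "a": 10,
                 "ror": 1.0, "ror_low": 0.5, "ror_high": 2.0,
                 "p_value": float(rng.random())}
            )
    out = signals.call_signals(_results_frame(rows))
    assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
    for drug, grp in out.groupby("drug"):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(grp["p_value"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(grp["p_adjusted"].to_numpy(), expected)


def test_suspicious_requires_both_frequentist_methods(pipeline_state):
    res = pipeline_state.signal_results
    assert (res["suspicious"] == (res["ror_positive"] & res["prr_positive"])).all()
    assert (res["positive_signal"] == res["bcpnn_positive"]).all()
    ok = res["ror_low"].notna()
    assert (res.loc[ok, "ror_low"] <= res.loc[ok, "ror"] + 1e-12).all()
    assert (res.loc[ok, "ror"] <= res.loc[ok, "ror_high"] + 1e-12).all()
    assert (res["ic025"] <= res["ic"]).all()
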