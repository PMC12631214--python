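"""Logistic risk model: VIF, Hosmer–Lemeshow, references, selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ocuvigil import riskmodel
from ocuvigil.errors import ConfigurationError
from ocuvigil.riskmodel import RegressionSpec


def simulate_cohort(
    n=5000,
    seed=0,
    beta=None,
    intercept=-2.0,
):
    """Draw a synthetic regression dataset with known log-odds effects."""
    rng = np.random.default_rng(seed)
    drug = rng.choice(
        ["Abemaciclib", "Palbociclib", "Ribociclib"], size=n, p=[0.15, 0.6, 0.25]
    )
    age = rng.integers(30, 90, size=n).astype(float)
    nc = rng.choice([0, 3, 8], size=n, p=[0.25, 0.45, 0.30]).astype(float)
    letro = rng.random(n) < 0.35
    beta = beta or {}
    lin = np.full(n, intercept)
    lin += np.log(beta.get("age_ge_65", 1.0)) * (age >= 65)
    lin += np.log(beta.get("drug_Palbociclib", 1.0)) * (drug == "Palbociclib")
    lin += np.log(beta.get("drug_Ribociclib", 1.0)) * (drug == "Ribociclib")
    lin += np.log(beta.get("conco_1_5", 1.0)) * ((nc > 0) & (nc <= 5))
    lin += np.log(beta.get("conco_gt5", 1.0)) * (nc > 5)
    lin += np.log(beta.get("letrozole_use", 1.0)) * letro
    p = 1 / (1 + np.exp(-lin))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "oae": y,
            "age_years": age,
            "drug": drug,
            "n_concomitant": nc,
            "letrozole_use": letro,
        }
    )


def test_fit_recovers_planted_letrozole_effect():
    data = simulate_cohort(n=20000, seed=1, beta={"letrozole_use": 1.5})
    res = riskmodel.fit_logistic(data)
    row = res.terms.set_index("term").loc["letrozole_use"]
    assert row["ci_low"] < 1.5 < row["ci_high"]
    assert res.converged
    assert res.n_used == 20000


def test_vif_orthogonal_design_is_one():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
    X = X - X.mean()
    # orthogonalise
    q, _ = np.linalg.qr(X.to_numpy())
    X = pd.DataFrame(q, columns=list("abc"))
    vif = riskmodel.compute_vif(X)
    assert np.allclose(vif, 1.0, atol=1e-8)


def test_vif_duplicated_column_is_infinite():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(100)
    X = pd.DataFrame({"a": x, "b": x})
    vif = riskmodel.compute_vif(X)
    assert np.isinf(vif["a"]) and np.isinf(vif["b"])


def test_vif_matches_ols_r2_oracle():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.standard_normal((400, 4)), columns=list("abcd"))
    X["d"] = X["a"] * 0.8 + rng.standard_normal(400) * 0.5
    vif = riskmodel.compute_vif(X)
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col))
        r2 = sm.OLS(X[col], others).fit().rsquared
        assert vif[col] == pytest.approx(1 / (1 - r2), rel=1e-8)


def test_hosmer_lemeshow_hand_computed_three_groups():
    # three risk strata of 10 with known observed counts
    p_hat = np.repeat([0.1, 0.4, 0.8], 10)
    y = np.concatenate([np.ones(2), np.zeros(8),   # obs 2, exp 1
                        np.ones
                        (3), np.zeros(7),          # obs 3, exp 4
                        np.ones(9), np.zeros(1)])  # obs 9, exp 8
    stat, p = riskmodel.hosmer_lemeshow(y, p_hat, g=3)
    expected = (
        (2 - 1) ** 2 / 1 + (8 - 9) ** 2 / 9
        + (3 - 4) ** 2 / 4 + (7 - 6) ** 2 / 6
        + (9 - 8) ** 2 / 8 + (1 - 2) ** 2 / 2
    )
    assert stat == pytest.approx(expected)
    from scipy import stats as sps

    assert p == pytest.approx(sps.chi2.sf(expected, df=1))


def test_hosmer_lemeshow_perfect_groups_zero():
    p_hat = np.repeat([0.2, 0.5, 0.8], 10)
    y = np.concatenate(
        [np.ones(2), np.zeros(8), np.ones(5), np.zeros(5), np.ones(8), np.zeros(2)]
    )
    stat, _ = riskmodel.hosmer_lemeshow(y, p_hat, g=3)
    assert stat == pytest.approx(0.0)


def test_hosmer_lemeshow_needs_three_groups():
    with pytest.raises(ConfigurationError):
        riskmodel.hosmer_lemeshow(np.array([0, 1]), np.array([0.1, 0.9]), g=2)


def test_hosmer_lemeshow_calibrated_model_rarely_rejects():
    rejections = 0
    for seed in range(60):
        data = simulate_cohort(n=3000, seed=100 + seed, beta={"letrozole_use": 1.4})
        res = riskmodel.fit_logistic(data)
        if res.hl_p < 0.05:
            rejections += 1
    # nominal 5% level: 60 trials, allow 3 SE above nominal
    assert rejections <= 60 * 0.05 + 3 * np.sqrt(60 * 0.05 * 0.95)


def test_reference_flip_inverts_odds_ratio():
    data = simulate_cohort(n=8000, seed=5, beta={"letrozole_use": 1.6})
    res = riskmodel.fit_logistic(data)
    flipped = data.assign(letrozole_use=~data["letrozole_use"].astype(bool))
    res2 = riskmodel.fit_logistic(flipped)
    or1 = res.terms.set_index("term").loc["letrozole_use", "odds_ratio"]
    or2 = res2.terms.set_index("term").loc["letrozole_use", "odds_ratio"]
    assert np.log(or1) == pytest.approx(-np.log(or2), abs=1e-9)


def test_zero_variance_covariate_dropped_with_warning():
    data = simulate_cohort(n=2000, seed=6)
    data["letrozole_use"] = False
    res = riskmodel.fit_logistic(data)
    assert "letrozole_use" not in set(res.terms["term"])
    assert any("zero-variance" in w for w in res.warnings)


def test_backward_selection_with_alpha_one_keeps_full_model():
    data = simulate_cohort(n=4000, seed=7, beta={"drug_Ribociclib": 1.5})
    full = riskmodel.fit_logistic(data, RegressionSpec(selection="none"))
    kept = riskmodel.fit_logistic(
        data, RegressionSpec(selection="backward", alpha_stay=1.0)
    )
    assert list(kept.terms["term"]) == list(full.terms["term"])
    np.testing.assert_allclose(
        kept.terms["odds_ratio"], full.terms["odds_ratio"], rtol=1e-9
    )


def test_backward_selection_never_drops_drug_term():
    # no real effects at all: everything droppable should go except drug
    data = simulate_cohort(n=3000, seed=8)
    res = riskmodel.fit_logistic(
        data, RegressionSpec(selection="backward", alpha_stay=0.05)
    )
    terms = set(res.terms["term"])
    assert {"drug_Palbociclib", "drug_Ribociclib"} <= terms
    assert all(t["dropped"] != "drug" for t in res.selection_trace)


def test_separation_flagged_not_fatal():
    n = 200
    rng = np.random.default_rng(9)
    data = pd.DataFrame(
        {
            "age_years": rng.integers(30, 90, n).astype(float),
            "drug": rng.choice(["Abemaciclib", "Palbociclib"], n),
            "n_concomitant": rng.integers(0, 10, n).astype(float),
            "letrozole_use": rng.random(n) < 0.5,
        }
    )
    data["oae"] = data["letrozole_use"].astype(int)  # perfect separation
    res = riskmodel.fit_logistic(data)
    assert not res.converged or res.warnings


def test_outcome_without_variation_is_error():
    data = simulate_cohort(n=500, seed=10)
    data["oae"] = 1
    with pytest.raises(ConfigurationError):
        riskmodel.fit_logistic(data)
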