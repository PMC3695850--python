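"""Predictive margins: GLM fits, standardization identities, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import cepanel as cp
from cepanel.margins import (fit_cost_glm, fit_eff_lm, predictive_margin,
                             adjusted_ce)


def _design(n, seed, gamma=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    g = (rng.random(n) < 0.5).astype(float)
    X = np.column_stack([np.ones(n), x, g])
    return X, x, g, rng


# -- fits -------------------------------------------------------------------

def test_gamma_intercept_only_recovers_sample_mean():
    rng = np.random.default_rng(0)
    y = rng.gamma(5.0, 40.0, size=400)
    fit = fit_cost_glm(np.ones((400, 1)), y, ["intercept"])
    assert np.exp(fit.params[0]) == pytest.approx(y.mean(), rel=1e-4)


def test_gamma_rejects_nonpositive_response():
    y = np.array([1.0, 2.0, 0.0, 3.0])
    with pytest.raises(ValueError, match="two-part"):
        fit_cost_glm(np.ones((4, 1)), y)


def test_duplicated_column_rank_error():
    X = np.ones((50, 2))
    y = np.full(50, 2.0)
    with pytest.raises(ValueError, match="rank"):
        fit_cost_glm(X, y, ["a", "b"])


def test_gamma_coefficient_recovery():
    n = 2000
    X, x, g, rng = _design(n, 1)
    beta = np.array([6.0, 0.3, -0.2])
    mu = np.exp(X @ beta)
    tau = 5.0
    y = rng.gamma(mu * tau) / tau
    fit = fit_cost_glm(X, y, ["intercept", "x", "group"])
    se = np.sqrt(fit.scale / n) * 3  # loose componentwise band
    assert np.all(np.abs(fit.params - beta) < np.maximum(se, 0.05))


def test_ols_intercept_only_and_exact_fit():
    y = np.array([1.0, 2.0, 3.0])
    fit = fit_eff_lm(np.ones((3, 1)), y)
    assert fit.params[0] == pytest.approx(2.0)
    # zero-variance response -> exact fit, sigma2 = 0
    fitc = fit_eff_lm(np.ones((3, 1)), np.full(3, 5.0))
    assert fitc.scale == pytest.approx(0.0, abs=1e-20)


def test_ols_recovery_on_linear_data():
    n = 2000
    X, x, g, rng = _design(n, 2)
    beta = np.array([1.0, 0.5, -0.3])
    y = X @ beta + rng.normal(0, 0.3, n)
    fit = fit_eff_lm(X, y, ["intercept", "x", "group"])
    assert np.all(np.abs(fit.params - beta) < 0.1)


# -- margin identities ------------------------------------------------------

def test_identity_link_margin_difference_equals_group_coefficient():
    n = 300
    X, x, g, rng = _design(n, 3)
    y = X @ np.array([1.0, 0.4, -0.6]) + rng.normal(0, 0.2, n)
    fit = fit_eff_lm(X, y, ["intercept", "x", "group"])
    diff = predictive_margin(fit, X, 0.0) - predictive_margin(fit, X, 1.0)
    assert diff == pytest.approx(-fit.params[2], abs=1e-12)


def test_log_link_margin_ratio_equals_exp_group_coefficient():
    n = 300
    X, x, g, rng = _design(n, 4)
    mu = np.exp(X @ np.array([5.0, 0.2, 0.3]))
    y = rng.gamma(mu * 4) / 4
    fit = fit_cost_glm(X, y, ["intercept", "x", "group"])
    ratio = predictive_margin(fit, X, 1.0) / predictive_margin(fit, X, 0.0)
    assert ratio == pytest.approx(np.exp(fit.params[2]), rel=1e-12)


def test_zero_group_coefficient_equal_margins():
    n = 200
    X, x, g, rng = _design(n, 5)
    fit = fit_eff_lm(X, X[:, 1] * 0.5 + 1.0, ["intercept", "x", "group"])
    assert predictive_margin(fit, X, 0.0) == pytest.approx(
        predictive_margin(fit, X, 1.0), abs=1e-10)


def test_margin_average_fitted_equals_response_mean():
    """Canonical-link GLM with intercept: average fitted value equals the
    sample mean of the response (margins on the unmodified design)."""
    n = 500
    X, x, g, rng = _design(n, 6)
    y = X @ np.array([0.7, 0.2, -0.1]) + rng.normal(0, 0.3, n)
    fit = fit_eff_lm(X, y, ["intercept", "x", "group"])
    assert fit.predict(X).mean() == pytest.approx(y.mean(), abs=1e-10)


def test_margins_match_brute_force_patient_by_patient(complete_ds):
    conf = ["gender", "diagnosis", "iip", "soc", "sas"]
    est = adjusted_ce(complete_ds, conf,
                      categorical=["gender", "diagnosis"])
    design = cp.build_design(complete_ds, conf,
                             categorical=["gender", "diagnosis"])
    co = cp.cumulative_outcomes(complete_ds)
    cost_fit = fit_cost_glm(design.cum_cost, co.cum_cost,
                            design.cols_cum_cost)
    eff_fit = fit_eff_lm(design.cum_eff, co.auc, design.cols_cum_eff)
    gc_c = design.cols_cum_cost.index("group")
    gc_e = design.cols_cum_eff.index("group")
    brute = {}
    for lv in (0.0, 1.0):
        Xc = design.cum_cost.copy()
        Xc[:, gc_c] = lv
        Xe = design.cum_eff.copy()
        Xe[:, gc_e] = lv
        brute[lv] = (np.mean([np.exp(r @ cost_fit.params) for r in Xc]),
                     np.mean([r @ eff_fit.params for r in Xe]))
    assert est.delta_cost == pytest.approx(brute[0.0][0] - brute[1.0][0])
    assert est.delta_eff == pytest.approx(brute[0.0][1] - brute[1.0][1])
    expect_icer = (brute[0.0][0] - brute[1.0][0]) / \
        (brute[0.0][1] - brute[1.0][1])
    assert est.icer == pytest.approx(expect_icer)


# -- adjusted CE ------------------------------------------------------------

def test_constant_group_errors(complete_ds):
    ds = complete_ds.copy()
    ds.group[:] = 0.0
    with pytest.raises(ValueError, match="both group levels"):
        adjusted_ce(ds, ["iip"])


def test_no_confounders_margins_collapse_to_group_means(complete_ds):
    """Intercept + group models: margins equal raw group means (AUC
    exactly; costs to GLM solver tolerance)."""
    est = adjusted_ce(complete_ds, [], baseline_adjustment=False)
    obs = cp.ce_summary(complete_ds)
    assert est.mean_eff["low"] == pytest.approx(obs.mean_eff["low"],
                                                abs=1e-6)
    assert est.mean_eff["high"] == pytest.approx(obs.mean_eff["high"],
                                                 abs=1e-6)
    assert est.mean_cost["low"] == pytest.approx(obs.mean_cost["low"],
                                                 rel=1e-5)
    assert est.mean_cost["high"] == pytest.approx(obs.mean_cost["high"],
                                                  rel=1e-5)


def test_adjusted_removes_confounding_bias():
    cfg = cp.null_effect_scenario(400)
    sim = cp.simulate_scenario(cfg, 17)
    obs = cp.ce_summary(sim.complete)
    adj = adjusted_ce(sim.complete, cfg.confounder_columns,
                      categorical=cfg.categorical)
    assert abs(adj.delta_eff) < abs(obs.delta_eff)


def test_bootstrap_adjusted_reproducible_and_consistent(complete_ds):
    conf = ["gender", "iip", "soc"]
    kw = dict(B=30, categorical=["gender"])
    a = cp.bootstrap_adjusted(complete_ds, conf,
                              rng=np.random.default_rng(2), **kw)
    b = cp.bootstrap_adjusted(complete_ds, conf,
                              rng=np.random.default_rng(2), **kw)
    assert a.delta_eff == b.delta_eff
    assert a.ci == b.ci
    assert a.extra["failed_replicates"] == b.extra["failed_replicates"]
    assert a.delta_cost == pytest.approx(
        a.mean_cost["low"] - a.mean_cost["high"], abs=1e-9)
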