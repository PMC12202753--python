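"""Null-model checks: closed forms, moment identities, external oracle."""

import numpy as np
import pytest
from scipy import special, stats

from pomskat.pom_null import (PomFitError, category_probs,
                              coef_standard_errors, fit_cumulative_logit,
                              fit_null, mean_response, var_response)
from pomskat.simdata import SimulationConfig, maf_grid, simulate_dataset


def test_intercept_only_binary_cutpoint_at_zero():
    y = np.repeat([0, 1], 50)
    fit = fit_null(y, None)
    assert fit.cutpoints[0] == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(fit.mu_hat, 0.5, atol=1e-6)


def test_intercept_only_equal_thirds_closed_form():
    y = np.repeat([0, 1, 2], 40)
    fit = fit_null(y, None)
    np.testing.assert_allclose(fit.cutpoints,
                               [special.logit(1 / 3), special.logit(2 / 3)],
                               atol=1e-6)
    probs = category_probs(fit)
    np.testing.assert_allclose(probs, 1 / 3, atol=1e-6)
    np.testing.assert_allclose(mean_response(fit), 1.0, atol=1e-6)
    np.testing.assert_allclose(var_response(fit), 2 / 3, atol=1e-6)


def test_binary_bernoulli_variance():
    # P(y=1)=0.3 for every subject -> mean 0.3, variance 0.21
    y = np.repeat([0, 1], [70, 30])
    fit = fit_null(y, None)
    np.testing.assert_allclose(mean_response(fit), 0.3, atol=1e-6)
    np.testing.assert_allclose(var_response(fit), 0.21, atol=1e-6)


def test_moment_identities_against_category_probs(small_dataset):
    """Exceedance-sum mean/variance equal sum jP and sum j^2 P - mu^2."""
    _, _, X, y, _ = small_dataset
    fit = fit_null(y, X)
    P = category_probs(fit, X)
    j = np.arange(fit.J)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(mean_response(fit, X), P @ j, atol=1e-12)
    np.testing.assert_allclose(var_response(fit, X),
                               P @ j**2 - (P @ j) ** 2, atol=1e-12)
    assert np.all(fit.var_hat > 0)
    assert np.all((fit.mu_hat > 0) & (fit.mu_hat < fit.J - 1))


def test_matches_statsmodels_ordered_model(small_dataset):
    """Independent MLE oracle: same coefficients, loglik and Wald SEs."""
    OrderedModel = pytest.importorskip(
        "statsmodels.miscmodels.ordinal_model").OrderedModel
    _, _, X, y, _ = small_dataset
    fit = fit_cumulative_logit(y, X)
    sm = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
    np.testing.assert_allclose(fit.coef, sm.params[:2], atol=5e-5)
    np.testing.assert_allclose(fit.cutpoints[0], sm.params[2], atol=5e-5)
    assert fit.loglik == pytest.approx(sm.llf, abs=1e-4)
    np.testing.assert_allclose(coef_standard_errors(fit, y, X),
                               sm.bse[:2], rtol=1e-3)


def test_binary_fit_equals_logistic_regression(rng):
    """For J=2 the cumulative-logit likelihood is the logistic one."""
    n = 400
    X = rng.standard_normal((n, 2))
    eta = X @ [0.8, -0.5]
    y = (rng.random(n) < special.expit(eta - 0.3)).astype(int)
    fit = fit_cumulative_logit(y, X)
    sm_api = pytest.importorskip("statsmodels.api")
    glm = sm_api.Logit(y, sm_api.add_constant(X)).fit(disp=0)
    # logit P(y=1) = -zeta + x'coef <-> intercept = -zeta
    np.testing.assert_allclose(-fit.cutpoints[0], glm.params[0], atol=1e-6)
    np.testing.assert_allclose(fit.coef, glm.params[1:], atol=1e-6)
    assert fit.loglik == pytest.approx(glm.llf, abs=1e-8)


def test_gamma_recovery_on_simulated_data():
    cfg = SimulationConfig(n=2000, M=2, J=3, rho=0.2, maf=(0.2, 0.3),
                           gamma=(0.5, 0.8), seed=21)
    G, X, y, _ = simulate_dataset(cfg, 0)
    fit = fit_cumulative_logit(y, X)
    se = coef_standard_errors(fit, y, X)
    assert np.all(np.abs(fit.coef - [0.5, 0.8]) < 3 * se)


def test_monte_carlo_moments(rng):
    """Simulated categories reproduce the analytic mean and variance."""
    y = np.repeat([0, 1, 2, 3], [50, 120, 90, 40])
    fit = fit_null(y, None)
    P = category_probs(fit)[0]
    draws = rng.choice(4, size=1_000_000, p=P)
    mu, var = mean_response(fit)[0], var_response(fit)[0]
    assert draws.mean() == pytest.approx(mu, abs=3 * np.sqrt(var / 1e6))
    assert draws.var() == pytest.approx(var, rel=0.01)


def test_loglik_is_a_maximum(small_dataset, rng):
    from pomskat.pom_null import _nll_grad
    _, _, X, y, _ = small_dataset
    fit = fit_cumulative_logit(y, X)
    raw = np.concatenate([[fit.cutpoints[0]],
                          np.log(np.diff(fit.cutpoints)), fit.coef])
    nll_opt = _nll_grad(raw, y, X, fit.J)[0]
    for _ in range(10):
        nll = _nll_grad(raw + 0.05 * rng.standard_normal(raw.size),
                        y, X, fit.J)[0]
        assert nll >= nll_opt - 1e-9


def test_input_validation_errors(small_dataset):
    _, _, X, y, _ = small_dataset
    with pytest.raises(ValueError, match="unobserved"):
        fit_null(np.where(y == 1, 2, y), X)     # level 1 empty
    with pytest.raises(PomFitError, match="rank deficient"):
        fit_null(y, np.column_stack([X, X[:, 0]]))
    with pytest.raises(ValueError):
        fit_null(y + 0.5, X)
    with pytest.raises(ValueError, match="start at 0"):
        fit_null(y + 1, X)
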