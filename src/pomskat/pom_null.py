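"""Cumulative-logit (proportional odds) model fitting and null moments.

The model is logit P(y <= j | x) = zeta_j - x'gamma with strictly ascending
cutpoints zeta_0 < ... < zeta_{J-2} (the polr/OrderedModel convention, so a
positive coefficient pushes probability mass toward higher categories).
Fitting maximizes the multinomial likelihood by quasi-Newton iteration on
the unconstrained parameterization (zeta_0, log successive gaps, gamma)
with an analytic gradient.

The set-based score test needs, per subject, the mean and variance of the
integer-scored response under the covariates-only null fit; both are
exceedance sums over the cutpoints:

    E(y_i)   = sum_{j=0}^{J-2} P(y_i > j)
    Var(y_i) = E(y_i) - E(y_i)^2 + 2 * sum_{j=1}^{J-2} j * P(y_i > j)

which are identical to sum_j j P(y=j) and sum_j j^2 P(y=j) - E(y)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "NullModelFit",
    "PomFitError",
    "fit_null",
    "fit_cumulative_logit",
    "category_probs",
    "mean_response",
    "var_response",
]

_GRAD_TOL = 1e-8      # target max-norm of the mean per-subject gradient
_CONV_TOL = 1e-5      # fits above this mean-gradient norm raise
_MAX_ITER = 200


class PomFitError(RuntimeError):
    """Raised when the cumulative-logit likelihood cannot be maximized."""


@dataclass(frozen=True)
class CumulativeLogitFit:
    """Raw MLE of a cumulative-logit model (any design matrix)."""

    cutpoints: np.ndarray   # zeta, strictly ascending, length J-1
    coef: np.ndarray        # effects of the design columns
    loglik: float
    converged: bool
    n_iter: int
    J: int


@dataclass(frozen=True)
class NullModelFit:
    """Covariates-only fit plus the per-subject null response moments."""

    cutpoints: np.ndarray
    gamma_hat: np.ndarray
    linear_predictor: np.ndarray
    mu_hat: np.ndarray
    var_hat: np.ndarray
    loglik: float
    converged: bool
    J: int


def _as_design(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None:
        return np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X row count must match the phenotype length")
    return X


def _validate_ordinal(y: np.ndarray) -> tuple[np.ndarray, int]:
    y = np.asarray(y)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a nonempty 1-d array")
    if not np.issubdtype(y.dtype, np.integer):
        yi = y.astype(np.int64)
        if not np.array_equal(yi, y):
            raise ValueError("y must hold integer category codes 0..J-1")
        y = yi
    J = int(y.max()) + 1
    if y.min() != 0:
        raise ValueError("category codes must start at 0")
    counts = np.bincount(y, minlength=J)
    missing = np.nonzero(counts == 0)[0]
    if missing.size:
        raise ValueError(
            f"phenotype category level(s) {missing.tolist()} are unobserved; "
            "recode to consecutive integers 0..J-1")
    if J < 2:
        raise ValueError("phenotype must have at least 2 observed categories")
    return y, J


def _unpack(params: np.ndarray, J: int) -> tuple[np.ndarray, np.ndarray]:
    """(zeta0, log-gaps, coef) -> (ascending zeta, coef)."""
    raw = params[: J - 1]
    zeta = np.empty(J - 1)
    zeta[0] = raw[0]
    if J > 2:
        zeta[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    return zeta, params[J - 1:]


def _pack_start(y: np.ndarray, J: int, K: int) -> np.ndarray:
    """Intercept-only start: cutpoints at marginal cumulative logits."""
    cum = np.cumsum(np.bincount(y, minlength=J))[:-1] / y.size
    zeta = special.logit(cum)
    raw = np.empty(J - 1)
    raw[0] = zeta[0]
    if J > 2:
        raw[1:] = np.log(np.maximum(np.diff(zeta), 1e-8))
    return np.concatenate([raw, np.zeros(K)])


def _nll_grad(params: np.ndarray, y: np.ndarray, X: np.ndarray,
              J: int) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in transformed coordinates."""
    n = y.size
    zeta, coef = _unpack(params, J)
    eta = X @ coef if coef.size else np.zeros(n)

    up = y <= J - 2          # subjects with a finite upper cutpoint
    lo = y >= 1              # subjects with a finite lower cutpoint
    Fu = np.ones(n)
    Fl = np.zeros(n)
    Fu[up] = special.expit(zeta[y[up]] - eta[up])
    Fl[lo] = special.expit(zeta[y[lo] - 1] - eta[lo])
    P = np.clip(Fu - Fl, 1e-300, None)
    nll = -np.log(P).sum()

    fu = np.zeros(n)
    fl = np.zeros(n)
    fu[up] = Fu[up] * (1.0 - Fu[up])
    fl[lo] = Fl[lo] * (1.0 - Fl[lo])
    # d nll / d zeta_k: -fu/P where y==k, +fl/P where y==k+1
    gz = (np.bincount(y[up], weights=-(fu / P)[up], minlength=J - 1)
          + np.bincount(y[lo] - 1, weights=(fl / P)[lo], minlength=J - 1))
    gz = gz[: J - 1]
    # chain rule onto (zeta0, log-gaps)
    graw = np.empty(J - 1)
    graw[0] = gz.sum()
    if J > 2:
        tail = np.cumsum(gz[::-1])[::-1]   # sum_{j>=k} gz[j]
        graw[1:] = np.exp(params[1: J - 1]) * tail[1:]
    geta = (fu - fl) / P                   # d nll / d eta_i
    gcoef = X.T @ geta if coef.size else np.empty(0)
    return nll, np.concatenate([graw, gcoef])


def fit_cumulative_logit(
    y: np.ndarray,
    X: np.ndarray | None,
    start: np.ndarray | None = None,
) -> CumulativeLogitFit:
    """MLE of the cumulative-logit model for an arbitrary design matrix.

    ``start`` optionally warm-starts the optimizer with the transformed
    parameter vector of a previous fit (used heavily by permutation loops).
    """
    y, J = _validate_ordinal(y)
    X = _as_design(X, y.size)
    K = X.shape[1]
    if K and start is None and \
            np.linalg.matrix_rank(np.column_stack([np.ones(y.size), X])) < K + 1:
        raise PomFitError("design matrix is rank deficient "
                          "(collinear columns or a constant column)")
    x0 = _pack_start(y, J, K) if start is None else np.asarray(start, float)
    res = optimize.minimize(
        _nll_grad, x0, args=(y, X, J), jac=True, method="BFGS",
        options={"gtol": _GRAD_TOL * y.size, "maxiter": _MAX_ITER})
    mean_grad = float(np.max(np.abs(res.jac))) / y.size
    converged = bool(res.success) or mean_grad < _CONV_TOL
    if not converged:
        raise PomFitError(
            f"cumulative-logit fit did not converge after {res.nit} "
            f"iterations (mean gradient max-norm {mean_grad:.2e}); "
            f"optimizer message: {res.message}")
    zeta, coef = _unpack(res.x, J)
    return CumulativeLogitFit(zeta, coef, -float(res.fun),
                              converged, int(res.nit), J)


def fit_hessian(fit: CumulativeLogitFit, y: np.ndarray,
                X: np.ndarray | None) -> np.ndarray:
    """Observed information in transformed coordinates at the MLE.

    Central finite differences of the analytic gradient; the coefficient
    block of its inverse is invariant to the cutpoint reparameterization,
    so Wald standard errors for the design-column effects read off directly.
    """
    y, J = _validate_ordinal(y)
    X = _as_design(X, y.size)
    raw = np.empty(J - 1)
    raw[0] = fit.cutpoints[0]
    if J > 2:
        raw[1:] = np.log(np.diff(fit.cutpoints))
    params = np.concatenate([raw, fit.coef])
    d = params.size
    H = np.empty((d, d))
    h = 1e-5
    for k in range(d):
        pp, pm = params.copy(), params.copy()
        pp[k] += h
        pm[k] -= h
        H[k] = (_nll_grad(pp, y, X, J)[1] - _nll_grad(pm, y, X, J)[1]) / (2 * h)
    return 0.5 * (H + H.T)


def coef_standard_errors(fit: CumulativeLogitFit, y: np.ndarray,
                         X: np.ndarray | None) -> np.ndarray:
    """Wald standard errors of the design-column coefficients."""
    H = fit_hessian(fit, y, X)
    cov = np.linalg.inv(H)
    K = fit.coef.size
    return np.sqrt(np.diag(cov)[-K:]) if K else np.empty(0)


def _cumulative_probs(cutpoints: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """n x (J-1) matrix of P(y <= j | x)."""
    return special.expit(cutpoints[None, :] - eta[:, None])


def fit_null(y: np.ndarray, X: np.ndarray | None) -> NullModelFit:
    """Fit the covariates-only proportional odds model (no SNP terms)."""
    y, J = _validate_ordinal(y)
    X = _as_design(X, y.size)
    fit = fit_cumulative_logit(y, X)
    eta = X @ fit.coef if fit.coef.size else np.zeros(y.size)
    F = _cumulative_probs(fit.cutpoints, eta)
    exceed = 1.0 - F                      # P(y > j), j = 0..J-2
    mu = exceed.sum(axis=1)
    j = np.arange(1, J - 1)
    var = mu - mu**2 + 2.0 * (exceed[:, 1:] * j[None, :]).sum(axis=1)
    return NullModelFit(fit.cutpoints, fit.coef, eta, mu, var,
                        fit.loglik, fit.converged, J)


def _fit_eta(fit: NullModelFit, X: np.ndarray | None) -> np.ndarray:
    if X is None:
        if fit.gamma_hat.size:
            raise ValueError("fit has covariates; X is required")
        return fit.linear_predictor
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X @ fit.gamma_hat if fit.gamma_hat.size else np.zeros(X.shape[0])


def category_probs(fit: NullModelFit, X: np.ndarray | None = None) -> np.ndarray:
    """n x J matrix of fitted category probabilities (rows sum to 1)."""
    eta = _fit_eta(fit, X)
    F = _cumulative_probs(fit.cutpoints, eta)
    full = np.column_stack([np.zeros(eta.size), F, np.ones(eta.size)])
    return np.diff(full, axis=1)


def mean_response(fit: NullModelFit, X: np.ndarray | None = None) -> np.ndarray:
    """E(y_i) under the fit: the exceedance sum over the J-1 cutpoints."""
    eta = _fit_eta(fit, X)
    return (1.0 - _cumulative_probs(fit.cutpoints, eta)).sum(axis=1)


def var_response(fit: NullModelFit, X: np.ndarray | None = None) -> np.ndarray:
    """Var(y_i) under the fit via the 2j-weighted exceedance sum."""
    eta = _fit_eta(fit, X)
    exceed = 1.0 - _cumulative_probs(fit.cutpoints, eta)
    mu = exceed.sum(axis=1)
    j = np.arange(1, fit.J - 1)
    return mu - mu**2 + 2.0 * (exceed[:, 1:] * j[None, :]).sum(axis=1)
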