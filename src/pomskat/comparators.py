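"""Baseline set-association tests: PCA-LRT, per-SNP MinP, Bonferroni, QT.

All four share the cumulative-logit machinery of :mod:`pomskat.pom_null`.
PCA reduces the SNP set to the leading principal components of the dosage
correlation matrix and likelihood-ratio tests their joint effect; MinP and
Bonferroni aggregate per-SNP Wald p-values; QT is the joint LRT of all M
SNP coefficients against chi-square with M degrees of freedom — the
classical test whose calibration degrades as M grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pom_null import (PomFitError, coef_standard_errors,
                       fit_cumulative_logit)
from .simdata import GenotypeMatrix

__all__ = [
    "PCAReduction",
    "pca_reduce",
    "pca_lrt_test",
    "single_snp_pvalues",
    "minp_permutation_test",
    "bonferroni_test",
    "qt_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCAReduction:
    """Leading principal components of the dosage correlation matrix."""

    scores: np.ndarray     # n x L component scores
    loadings: np.ndarray   # M x L unit-norm eigenvectors
    explained: np.ndarray  # eigenvalue proportions of the retained components
    L: int


def _dosages(G: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(G, GenotypeMatrix):
        return np.asarray(G.dosages, dtype=float), list(G.snp_ids)
    d = np.asarray(G, dtype=float)
    return d, [f"snp{m + 1}" for m in range(d.shape[1])]


def _augment(X: np.ndarray | None, extra: np.ndarray) -> np.ndarray:
    if extra.ndim == 1:
        extra = extra[:, None]
    if X is None:
        return extra
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([extra, X])


def pca_reduce(G: GenotypeMatrix | np.ndarray,
               threshold: float = 0.80) -> PCAReduction:
    """PCA on standardized dosages, keeping the smallest L components whose
    cumulative eigenvalue proportion reaches ``threshold``."""
    dos, ids = _dosages(G)
    sd = dos.std(axis=0)
    if np.any(sd == 0):
        bad = [ids[m] for m in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant genotype column(s): {', '.join(bad)}")
    Z = (dos - dos.mean(axis=0)) / sd
    M = Z.shape[1]
    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    prop = eigval / eigval.sum()
    L = int(np.searchsorted(np.cumsum(prop), threshold) + 1)
    L = min(L, M)
    return PCAReduction(scores=Z @ eigvec[:, :L], loadings=eigvec[:, :L],
                        explained=prop[:L], L=L)


def pca_lrt_test(y: np.ndarray, X: np.ndarray | None,
                 G: GenotypeMatrix | np.ndarray,
                 threshold: float = 0.80) -> float:
    """LRT of the leading principal components in the proportional odds
    model, referred to chi-square with L degrees of freedom."""
    red = pca_reduce(G, threshold)
    null = fit_cumulative_logit(y, X)
    full = fit_cumulative_logit(y, _augment(X, red.scores))
    lrt = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(stats.chi2.sf(lrt, red.L))


def single_snp_pvalues(y: np.ndarray, X: np.ndarray | None,
                       G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-SNP Wald p-values from one-SNP proportional odds fits.

    Each SNP is tested marginally (with covariates); the Wald statistic
    beta_hat / SE is referred to a standard normal.  SNPs whose fit fails
    yield NaN and a logged warning.
    """
    dos, ids = _dosages(G)
    M = dos.shape[1]
    out = np.full(M, np.nan)
    for m in range(M):
        design = _augment(X, dos[:, m])
        try:
            fit = fit_cumulative_logit(y, design)
            se = coef_standard_errors(fit, y, design)
            z = fit.coef[0] / se[0]
            out[m] = 2.0 * stats.norm.sf(abs(z))
        except (PomFitError, ValueError, np.linalg.LinAlgError) as err:
            logger.warning("single-SNP fit failed for %s: %s", ids[m], err)
    return out


def minp_permutation_test(y: np.ndarray, X: np.ndarray | None,
                          G: GenotypeMatrix | np.ndarray,
                          R: int = 1000,
                          seed: int | np.random.Generator = 0) -> float:
    """Permutation reference for the minimum per-SNP p-value.

    The phenotype vector alone is shuffled R times (breaking both the
    genotype and covariate coupling); the returned p-value is
    ``(1 + #{min_p_perm <= min_p_obs}) / (R + 1)``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    obs = single_snp_pvalues(y, X, G)
    if np.all(np.isnan(obs)):
        raise ValueError("every per-SNP fit failed; MinP undefined")
    minp = np.nanmin(obs)
    hits = 0
    for _ in range(R):
        perm = single_snp_pvalues(rng.permutation(np.asarray(y)), X, G)
        if np.nanmin(perm) <= minp:
            hits += 1
    return (1 + hits) / (R + 1)


def bonferroni_test(pvalues: np.ndarray) -> float:
    """Bonferroni-adjusted minimum p-value, min(1, M * min p)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    return float(min(1.0, p.size * p.min()))


def qt_test(y: np.ndarray, X: np.ndarray | None,
            G: GenotypeMatrix | np.ndarray) -> float:
    """Joint LRT of all M SNP coefficients against chi-square(M).

    Requires the joint fit to be estimable (n much larger than M and no
    collinear dosage columns); with many SNPs this classical test is
    exactly the regime where its calibration is known to fail.
    """
    dos, _ = _dosages(G)
    n, M = dos.shape
    K = 0 if X is None else np.atleast_2d(np.asarray(X).T).shape[0]
    J = int(np.max(y)) + 1
    if n <= M + K + J:
        raise ValueError(f"joint fit with M={M} SNPs and n={n} subjects "
                         "is not estimable")
    null = fit_cumulative_logit(y, X)
    try:
        full = fit_cumulative_logit(y, _augment(X, dos))
    except PomFitError as err:
        raise PomFitError(f"joint {M}-SNP fit failed: {err}") from err
    lrt = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(stats.chi2.sf(lrt, M))
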