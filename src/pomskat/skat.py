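"""Variance-component score test for SNP sets with an ordinal phenotype.

The SNP coefficients beta are modeled as random with mean zero and variance
D(theta); testing all M coefficients at once reduces to testing the single
variance parameter, H0: theta = 0.  The score statistic is the weighted
quadratic form

    T = 1/2 * (y - mu)' Gt W Gt' (y - mu)

where mu is the fitted null mean of the integer-scored ordinal response,
Gt is the genotype matrix residualized on an intercept and the covariates,
and W = diag(w_m) holds squared Beta(1/2, 1/2) density weights evaluated at
each SNP's folded minor-allele frequency.  Under H0, T is distributed as a
mixture sum_m lambda_m chi2_1 whose coefficients are the eigenvalues of
1/2 V^{1/2} Gt W Gt' V^{1/2} (V = diag of the null response variances);
the tail probability is approximated by a Pearson Type III (shifted gamma)
distribution matched to the mixture's first three moments, which is exact
when a single eigenvalue remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pom_null import NullModelFit, PomFitError, fit_cumulative_logit, fit_null
from .simdata import GenotypeMatrix

__all__ = [
    "KernelWeights",
    "MixtureSpectrum",
    "PearsonIIIParams",
    "TestResult",
    "beta_weights",
    "residualize_genotypes",
    "skat_statistic",
    "mixture_eigenvalues",
    "pearson3_params",
    "pearson3_pvalue",
    "permutation_pvalue",
    "pom_skat_test",
]

logger = logging.getLogger(__name__)

_EIG_RTOL = 1e-10   # eigenvalues below this fraction of the largest are noise


@dataclass(frozen=True)
class KernelWeights:
    """Per-SNP kernel weights: the diagonal of the variance derivative."""

    weights: np.ndarray
    maf_used: np.ndarray
    spec: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.size == 0 or not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be finite and strictly positive")


@dataclass(frozen=True)
class MixtureSpectrum:
    """Eigenvalues of the null chi-square mixture and its first moments."""

    lambdas: np.ndarray   # nonincreasing, strictly positive
    ET: float             # sum lambda
    VarT: float           # 2 sum lambda^2
    M3: float             # 8 sum lambda^3 = E[(T - ET)^3]
    xi: float             # skewness, M3 / VarT^{3/2}

    @classmethod
    def from_lambdas(cls, lambdas: np.ndarray) -> "MixtureSpectrum":
        lam = np.sort(np.asarray(lambdas, dtype=float))[::-1]
        if lam.size == 0 or lam[-1] <= 0:
            raise ValueError("spectrum requires strictly positive eigenvalues")
        ET = float(lam.sum())
        VarT = float(2.0 * (lam**2).sum())
        M3 = float(8.0 * (lam**3).sum())
        return cls(lam, ET, VarT, M3, M3 / VarT**1.5)


@dataclass(frozen=True)
class PearsonIIIParams:
    """Shifted-gamma (Pearson Type III) parameters matched to (0, 1, xi)."""

    scale_a: float
    shape_b: float
    location_c: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of one set-based test, with all intermediates."""

    statistic_T: float
    T_star: float
    p_value: float
    spectrum: MixtureSpectrum
    method: str
    n: int
    M: int
    J: int
    M_used: int
    M_dropped: int
    set_name: str = "set"
    dropped_snps: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.statistic_T < 0:
            raise ValueError("statistic must be nonnegative")

    @property
    def xi(self) -> float:
        return self.spectrum.xi


def beta_weights(maf: np.ndarray, a: float = 0.5,
                 b: float = 0.5) -> KernelWeights:
    """Squared Beta(a, b) density evaluated at folded MAFs.

    With the default a = b = 1/2 the density is 1 / (pi sqrt(f (1-f))),
    so rarer SNPs receive larger weights.
    """
    f = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any((f <= 0.0) | (f >= 1.0)):
        bad = np.nonzero((f <= 0.0) | (f >= 1.0))[0]
        raise ValueError(
            f"monomorphic SNP(s) at index {bad.tolist()}: MAF must lie "
            "strictly inside (0, 1); drop these SNPs before weighting")
    folded = np.minimum(f, 1.0 - f)
    return KernelWeights(stats.beta.pdf(folded, a, b) ** 2, folded, (a, b))


def _dosage_array(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    d = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
    return np.asarray(d, dtype=float)


def residualize_genotypes(G: GenotypeMatrix | np.ndarray,
                          X: np.ndarray | None) -> np.ndarray:
    """Residuals of each dosage column on [intercept, covariates].

    The projection removes covariate-genotype confounding and centers
    every column, which the score statistic requires even without
    covariates.
    """
    dos = _dosage_array(G)
    n = dos.shape[0]
    if X is None:
        design = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient")
    Q, _ = np.linalg.qr(design)
    return dos - Q @ (Q.T @ dos)


def skat_statistic(y: np.ndarray, mu_hat: np.ndarray, G_tilde: np.ndarray,
                   weights: KernelWeights | np.ndarray) -> float:
    """T = 1/2 sum_m w_m (gt_m' (y - mu))^2, column-wise (no n x n kernel)."""
    w = weights.weights if isinstance(weights, KernelWeights) else np.asarray(weights)
    r = np.asarray(y, dtype=float) - np.asarray(mu_hat, dtype=float)
    s = np.asarray(G_tilde).T @ r
    return float(0.5 * np.dot(w, s**2))


def mixture_eigenvalues(G_tilde: np.ndarray,
                        weights: KernelWeights | np.ndarray,
                        var_hat: np.ndarray) -> MixtureSpectrum:
    """Eigenvalues of the null mixture, via the M x M symmetric form.

    1/2 W^{1/2} Gt' V Gt W^{1/2} shares all nonzero eigenvalues with the
    n x n matrix 1/2 V^{1/2} Gt W Gt' V^{1/2}; eigenvalues below
    1e-10 of the largest are treated as numerical rank deficiency.
    """
    w = weights.weights if isinstance(weights, KernelWeights) else np.asarray(weights)
    v = np.asarray(var_hat, dtype=float)
    if np.any(v <= 0):
        raise ValueError("null response variances must be strictly positive")
    C = np.asarray(G_tilde) * np.sqrt(w)[None, :]
    K = 0.5 * (C.T @ (v[:, None] * C))
    lam = np.linalg.eigvalsh(K)[::-1]
    lam = lam[lam > _EIG_RTOL * max(lam[0], 0.0)]
    if lam.size == 0:
        raise ValueError("empty mixture spectrum: every SNP column is "
                         "degenerate after residualization")
    return MixtureSpectrum.from_lambdas(lam)


def pearson3_params(xi: float) -> PearsonIIIParams:
    """Shifted gamma with mean 0, variance 1 and skewness xi.

    Matching X = c + a * Gamma(shape b, scale 1) to those moments gives
    shape b = 4/xi^2, scale a = xi/2, location c = -2/xi; as xi -> 0 the
    matched distribution tends to the standard normal.
    """
    if not xi > 0:
        raise ValueError("skewness must be strictly positive")
    return PearsonIIIParams(scale_a=xi / 2.0, shape_b=4.0 / xi**2,
                            location_c=-2.0 / xi)


def pearson3_pvalue(T: float, spectrum: MixtureSpectrum) -> float:
    """Upper-tail Pearson III probability of the standardized statistic."""
    par = pearson3_params(spectrum.xi)
    t_star = (T - spectrum.ET) / np.sqrt(spectrum.VarT)
    # gamma.sf is 1 for arguments below the support, handling T* < c
    return float(stats.gamma.sf((t_star - par.location_c) / par.scale_a,
                                par.shape_b))


def _standardized(T: float, spectrum: MixtureSpectrum) -> float:
    return float((T - spectrum.ET) / np.sqrt(spectrum.VarT))


def _drop_degenerate(G: GenotypeMatrix | np.ndarray,
                     X: np.ndarray | None,
                     set_name: str) -> tuple[np.ndarray, np.ndarray,
                                             list[str], list[str]]:
    """Residualize and drop monomorphic / zero-residual SNP columns."""
    dos = _dosage_array(G)
    ids = list(G.snp_ids) if isinstance(G, GenotypeMatrix) else [
        f"snp{m + 1}" for m in range(dos.shape[1])]
    p = dos.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > 0.0
    Gt = residualize_genotypes(dos, X)
    # columns lying exactly in the covariate span carry no signal
    keep &= (Gt**2).sum(axis=0) > 1e-10 * dos.shape[0]
    dropped = [s for s, k in zip(ids, keep) if not k]
    if dropped:
        logger.warning("set %s: dropped %d degenerate SNP(s): %s",
                       set_name, len(dropped), ", ".join(dropped))
    if not keep.any():
        raise ValueError(f"set {set_name}: no usable SNPs remain "
                         "(all monomorphic or collinear with covariates)")
    kept = [s for s, k in zip(ids, keep) if k]
    return Gt[:, keep], maf[keep], kept, dropped


def pom_skat_test(
    y: np.ndarray,
    X: np.ndarray | None,
    G: GenotypeMatrix | np.ndarray,
    weight_spec: tuple[float, float] | KernelWeights = (0.5, 0.5),
    set_name: str = "set",
) -> TestResult:
    """End-to-end set test: null fit, weights, statistic, Pearson III p.

    ``weight_spec`` is either ``(a, b)`` for Beta-density weights computed
    from the sample MAFs of the retained SNPs, or a prebuilt
    :class:`KernelWeights` aligned with the columns of ``G``.
    """
    dos = _dosage_array(G)
    M_total = dos.shape[1]
    try:
        null = fit_null(y, X)
    except (ValueError, PomFitError) as err:
        raise type(err)(f"set {set_name}: null model fit failed: {err}") from err
    Gt, maf, kept, dropped = _drop_degenerate(G, X, set_name)
    if isinstance(weight_spec, KernelWeights):
        w_all = np.asarray(weight_spec.weights)
        if w_all.size != M_total:
            raise ValueError("prebuilt weights must align with G columns")
        keep_idx = [i for i, s in enumerate(
            G.snp_ids if isinstance(G, GenotypeMatrix)
            else [f"snp{m + 1}" for m in range(M_total)]) if s in set(kept)]
        weights = KernelWeights(w_all[keep_idx], weight_spec.maf_used[keep_idx],
                                weight_spec.spec)
    else:
        weights = beta_weights(maf, *weight_spec)
    T = skat_statistic(y, null.mu_hat, Gt, weights)
    spectrum = mixture_eigenvalues(Gt, weights, null.var_hat)
    p = pearson3_pvalue(T, spectrum)
    return TestResult(
        statistic_T=T, T_star=_standardized(T, spectrum), p_value=p,
        spectrum=spectrum, method="POM-SKAT", n=dos.shape[0], M=M_total,
        J=null.J, M_used=len(kept), M_dropped=len(dropped),
        set_name=set_name, dropped_snps=tuple(dropped))


def permutation_pvalue(
    y: np.ndarray,
    X: np.ndarray | None,
    G: GenotypeMatrix | np.ndarray,
    weights: KernelWeights | tuple[float, float] = (0.5, 0.5),
    H: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Re-sampling p-value: refit the null per permuted phenotype.

    The residualized genotypes and weights depend only on (G, X) and are
    computed once; each permutation refits the covariates-only model and
    re-evaluates T.  Permutations that empty a category are redrawn (and
    logged).  Returns ``(1 + #{T_perm >= T_obs}) / (H + 1)``.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("phenotype has no variation; permutation p-value "
                         "is undefined")
    Gt, maf, _, _ = _drop_degenerate(G, X, "perm")
    w = weights if isinstance(weights, KernelWeights) else beta_weights(maf, *weights)
    null = fit_null(y, X)
    T_obs = skat_statistic(y, null.mu_hat, Gt, w)
    J = null.J
    wvec = w.weights
    # warm-start every permuted refit at the observed optimum
    start = np.empty(J - 1 + null.gamma_hat.size)
    start[0] = null.cutpoints[0]
    if J > 2:
        start[1: J - 1] = np.log(np.diff(null.cutpoints))
    start[J - 1:] = null.gamma_hat
    Xd = np.empty((len(y), 0)) if X is None else np.atleast_2d(np.asarray(X, float))
    if Xd.ndim == 2 and Xd.shape[0] != len(y):
        Xd = Xd.T
    from scipy.special import expit
    exceed = 0
    redrawn = 0
    for _ in range(H):
        while True:
            yp = rng.permutation(y)
            if np.bincount(yp, minlength=J).min() > 0:
                break
            redrawn += 1
        fit_p = fit_cumulative_logit(yp, X, start=start)
        eta = Xd @ fit_p.coef if fit_p.coef.size else np.zeros(yp.size)
        mu_p = (1.0 - expit(fit_p.cutpoints[None, :] - eta[:, None])).sum(axis=1)
        if skat_statistic(yp, mu_p, Gt, wvec) >= T_obs:
            exceed += 1
    if redrawn:
        logger.info("permutation test: redrew %d degenerate permutations",
                    redrawn)
    return (1 + exceed) / (H + 1)
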