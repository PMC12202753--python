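"""Synthetic genotype/phenotype generator for the simulation studies.

Genotypes come from a Gaussian-copula construction: a latent AR(1)
multivariate normal vector is thresholded per SNP at the standard-normal
quantiles of (1-f)^2 and 1-f^2, so each dosage column has Hardy-Weinberg
marginals (1-f)^2 : 2f(1-f) : f^2 while adjacent SNPs carry LD controlled
by the latent correlation rho.  Phenotypes are ordinal: a continuous latent
trait (linear in covariates and the first B SNP dosages, logistic(0,1)
errors, optional pairwise dosage interaction) is cut at its own empirical
quantiles, which pins the category proportions exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "maf_grid",
    "gen_genotypes",
    "gen_covariates",
    "gen_ordinal_phenotype",
    "simulate_dataset",
    "replicate_rng",
]

# covariates are bivariate normal with unit variances and correlation 0.5
_COVAR_COV = np.array([[1.0, 0.5], [0.5, 1.0]])


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation scenario.

    Parameters
    ----------
    n : subject count.
    M : SNP count.
    J : number of ordered phenotype categories (>= 2).
    rho : latent AR(1) correlation between adjacent SNPs, in [0, 1).
    maf : M minor-allele frequencies in (0, 0.5].
    gamma : covariate effects on the latent trait (length 2).
    beta : effects of the first ``len(beta)`` SNPs on the latent trait.
    phi : coefficient of the g1*g2 interaction term (0 disables it).
    D : J-1 strictly increasing quantile probabilities in (0, 1) at which
        the latent trait is cut into categories.
    seed : master seed; replicate streams are spawned from it.
    """

    n: int
    M: int
    J: int
    rho: float
    maf: tuple[float, ...]
    gamma: tuple[float, ...] = (0.5, 0.8)
    beta: tuple[float, ...] = ()
    phi: float = 0.0
    D: tuple[float, ...] = (0.16, 0.84)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "maf", tuple(float(f) for f in self.maf))
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        object.__setattr__(self, "D", tuple(float(d) for d in self.D))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if len(self.maf) != self.M:
            raise ValueError("maf must have length M")
        if any(not 0.0 < f <= 0.5 for f in self.maf):
            raise ValueError("maf values must lie in (0, 0.5]")
        if len(self.D) != self.J - 1:
            raise ValueError("D must have length J-1")
        d = np.asarray(self.D)
        if not (np.all(np.diff(d) > 0) and d[0] > 0 and d[-1] < 1):
            raise ValueError("D must be strictly increasing within (0, 1)")
        if len(self.beta) > self.M:
            raise ValueError("beta cannot be longer than M")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x M additive dosage matrix with SNP ids and observed folded MAFs."""

    dosages: np.ndarray
    snp_ids: tuple[str, ...]
    maf: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if not np.isin(d, (0, 1, 2)).all():
            raise ValueError("dosages must take values in {0, 1, 2}")
        if len(self.snp_ids) != d.shape[1]:
            raise ValueError("snp_ids length must match the SNP dimension")

    @classmethod
    def from_dosages(cls, dosages: np.ndarray,
                     snp_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        d = np.ascontiguousarray(np.asarray(dosages, dtype=np.int8))
        if snp_ids is None:
            snp_ids = tuple(f"snp{m + 1}" for m in range(d.shape[1]))
        p = d.mean(axis=0) / 2.0
        return cls(d, tuple(str(s) for s in snp_ids), np.minimum(p, 1.0 - p))

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def M(self) -> int:
        return self.dosages.shape[1]


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent stream for one replicate, a pure function of (seed, r)."""
    if replicate < 0:
        raise ValueError("replicate index must be nonnegative")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed),
                               spawn_key=(int(replicate),)))


def maf_grid(M: int, lo: float = 0.1, hi: float = 0.45) -> np.ndarray:
    """M equally spaced allele frequencies from lo to hi inclusive."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0.0 < lo <= hi or hi >= 0.5 + 1e-12:
        raise ValueError("need 0 < lo <= hi < 0.5")
    if M == 1:
        return np.array([lo])
    return np.linspace(lo, hi, M)


def _latent_ar1(n: int, M: int, rho: float,
                rng: np.random.Generator) -> np.ndarray:
    """n x M standard-normal matrix with AR(1) row covariance rho^|j-k|."""
    eps = rng.standard_normal((n, M))
    if rho == 0.0 or M == 1:
        return eps
    z = np.empty((n, M))
    z[:, 0] = eps[:, 0]
    s = np.sqrt(1.0 - rho * rho)
    for m in range(1, M):  # exact AR(1) recursion, O(nM)
        z[:, m] = rho * z[:, m - 1] + s * eps[:, m]
    return z


def gen_genotypes(n: int, M: int, rho: float, maf: Sequence[float],
                  rng: np.random.Generator | int) -> GenotypeMatrix:
    """Dosages via thresholding an AR(1) latent normal at HWE quantiles.

    SNP m with allele frequency f is coded 0 when the latent value is at or
    below the (1-f)^2 normal quantile, 2 above the 1-f^2 quantile, else 1.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    maf = np.asarray(maf, dtype=float)
    if maf.shape != (M,):
        raise ValueError("maf must have length M")
    if np.any(maf <= 0.0) or np.any(maf >= 1.0):
        raise ValueError("allele frequencies must lie in (0, 1)")
    z = _latent_ar1(n, M, rho, rng)
    q1 = stats.norm.ppf((1.0 - maf) ** 2)
    q2 = stats.norm.ppf(1.0 - maf**2)
    dosages = (z > q1).astype(np.int8) + (z > q2).astype(np.int8)
    return GenotypeMatrix.from_dosages(dosages)


def gen_covariates(n: int, rng: np.random.Generator | int) -> np.ndarray:
    """n i.i.d. bivariate-normal covariate rows, unit variance, cov 0.5."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n < 1:
        raise ValueError("n must be >= 1")
    chol = np.linalg.cholesky(_COVAR_COV)
    return rng.standard_normal((n, 2)) @ chol.T


def gen_ordinal_phenotype(
    G: GenotypeMatrix | np.ndarray,
    X: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent trait + logistic noise, cut at its empirical quantiles.

    Returns ``(y, latent)`` where ``y`` holds categories 0..J-1.  The
    cutpoints are the empirical quantiles (linear interpolation between
    order statistics) of the realized latent trait at probabilities
    ``config.D``, so category proportions match diff(0, D, 1) up to
    rounding regardless of the effect sizes.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    dos = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
    X = np.asarray(X, dtype=float)
    n = dos.shape[0]
    latent = X @ np.asarray(config.gamma)
    if config.beta:
        B = len(config.beta)
        latent = latent + dos[:, :B] @ np.asarray(config.beta)
    if config.phi != 0.0:
        # raw (uncentered) dosage product, matching the latent-trait model
        latent = latent + config.phi * dos[:, 0] * dos[:, 1]
    latent = latent + rng.logistic(loc=0.0, scale=1.0, size=n)
    cutpoints = np.quantile(latent, config.D)
    y = np.digitize(latent, cutpoints)  # y > cutpoint -> next category
    return y.astype(np.int64), latent


def simulate_dataset(
    config: SimulationConfig,
    replicate: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray, np.ndarray]:
    """One full replicate ``(G, X, y, latent)`` from its own seed stream."""
    rng = replicate_rng(config.seed, replicate)
    G = gen_genotypes(config.n, config.M, config.rho, config.maf, rng)
    X = gen_covariates(config.n, rng)
    y, latent = gen_ordinal_phenotype(G, X, config, rng)
    return G, X, y, latent
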