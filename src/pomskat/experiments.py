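"""Simulation harness: type I error sweeps, power grids, Q-Q data.

A scenario is a :class:`~pomskat.simdata.SimulationConfig`; each replicate
draws fresh genotypes, covariates and phenotype from its own seed stream
and records the p-value of one or more tests.  Rejection rates at a level
alpha come with binomial Monte-Carlo standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import comparators
from .pom_null import PomFitError
from .simdata import SimulationConfig, maf_grid, simulate_dataset
from .skat import pom_skat_test

__all__ = [
    "ExperimentResult",
    "table1_scenarios",
    "type1_experiment",
    "power_experiment",
    "qq_data",
]

logger = logging.getLogger(__name__)

POWER_METHODS = ("POM-SKAT", "PCA", "BC", "QT")


@dataclass(frozen=True)
class ExperimentResult:
    """Rejection rate of one method over repeated simulations."""

    config: SimulationConfig
    method: str
    reps: int
    pvalues: np.ndarray
    alpha: float
    failures: int = 0

    @property
    def rejection_rate(self) -> float:
        return float(np.mean(self.pvalues <= self.alpha))

    @property
    def mc_se(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1.0 - r) / self.reps))


def table1_scenarios(seed: int = 0) -> list[SimulationConfig]:
    """The 18 null scenarios: J=3 (n=2000) and J=5 (n=3000) crossed with
    M in {50, 100, 200} and rho in {0.2, 0.5, 0.8}."""
    out = []
    for J, n, D in ((3, 2000, (0.16, 0.84)),
                    (5, 3000, (0.2, 0.4, 0.6, 0.8))):
        for M in (50, 100, 200):
            for rho in (0.2, 0.5, 0.8):
                out.append(SimulationConfig(
                    n=n, M=M, J=J, rho=rho, maf=tuple(maf_grid(M)),
                    gamma=(0.5, 0.8), beta=(), D=D, seed=seed))
    return out


def _replicate_pvalue(config: SimulationConfig, r: int, method: str,
                      qt_max_M: int | None = None) -> float:
    G, X, y, _ = simulate_dataset(config, replicate=r)
    if method == "POM-SKAT":
        return pom_skat_test(y, X, G).p_value
    if method == "PCA":
        return comparators.pca_lrt_test(y, X, G)
    if method == "BC":
        return comparators.bonferroni_test(
            comparators.single_snp_pvalues(y, X, G))
    if method == "QT":
        if qt_max_M is not None and config.M > qt_max_M:
            raise ValueError(f"QT disabled for M > {qt_max_M}")
        return comparators.qt_test(y, X, G)
    raise ValueError(f"unknown method {method!r}")


def _run(config: SimulationConfig, reps: int, alpha: float,
         method: str) -> ExperimentResult:
    pvals = np.empty(reps)
    failures = 0
    r = 0
    draw = 0
    while r < reps:
        try:
            pvals[r] = _replicate_pvalue(config, draw, method)
            r += 1
        except PomFitError as err:
            failures += 1
            logger.warning("%s replicate %d failed (%s); redrawing",
                           method, draw, err)
            if failures > reps:
                raise
        draw += 1
    if failures:
        logger.info("%s: %d replicate(s) redrawn after fit failure",
                    method, failures)
    return ExperimentResult(config, method, reps, pvals, alpha, failures)


def type1_experiment(config: SimulationConfig, reps: int = 500,
                     alpha: float = 0.05) -> ExperimentResult:
    """Null rejection rate of POM-SKAT; requires an effect-free config."""
    if config.beta or config.phi != 0.0:
        raise ValueError("type I error scenarios must have beta empty "
                         "and phi = 0")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return _run(config, reps, alpha, "POM-SKAT")


def power_experiment(config: SimulationConfig, reps: int = 500,
                     alpha: float = 0.05,
                     methods: tuple[str, ...] = POWER_METHODS,
                     ) -> dict[str, ExperimentResult]:
    """Rejection rates of several tests under one alternative scenario."""
    unknown = set(methods) - set(POWER_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    return {m: _run(config, reps, alpha, m) for m in methods}


def qq_data(pvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired (-log10 theoretical, -log10 observed) Q-Q quantiles.

    Observed p-values are sorted ascending and paired with uniform
    plotting positions i/(n+1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.ptp(p) == 0:
        raise ValueError("degenerate input: all p-values identical")
    obs = np.sort(p)
    theo = np.arange(1, p.size + 1) / (p.size + 1)
    with np.errstate(divide="ignore"):
        return -np.log10(theo), -np.log10(obs)
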