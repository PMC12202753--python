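"""Core-test checks: weights, statistic, spectrum, Pearson III, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pomskat.pom_null import fit_null
from pomskat.simdata import (GenotypeMatrix, SimulationConfig, maf_grid,
                             simulate_dataset)
from pomskat.skat import (KernelWeights, MixtureSpectrum, beta_weights,
                          mixture_eigenvalues, pearson3_params,
                          pearson3_pvalue, permutation_pvalue, pom_skat_test,
                          residualize_genotypes, skat_statistic)


@pytest.mark.parametrize("maf, weight", [
    (0.5, (2 / np.pi) ** 2),                    # density 2/pi
    (0.1, (1 / (0.3 * np.pi)) ** 2),            # density 1/(0.3 pi)
    (0.25, (1 / (np.pi * np.sqrt(0.1875))) ** 2),
])
def test_beta_weight_closed_forms(maf, weight):
    assert beta_weights([maf]).weights[0] == pytest.approx(weight, rel=1e-6)


def test_beta_weights_fold_and_reject_monomorphic():
    w = beta_weights([0.9])
    assert w.maf_used[0] == pytest.approx(0.1)
    assert w.weights[0] == pytest.approx(beta_weights([0.1]).weights[0])
    with pytest.raises(ValueError, match="monomorphic"):
        beta_weights([0.0, 0.3])


def test_residualize_centers_without_covariates():
    g = np.array([[0.0], [1.0], [2.0], [1.0]])
    np.testing.assert_allclose(residualize_genotypes(g, None),
                               [[-1], [0], [1], [0]], atol=1e-12)


def test_residualize_orthogonality(small_dataset):
    _, G, X, _, _ = small_dataset
    Gt = residualize_genotypes(G, X)
    assert np.abs(Gt.sum(axis=0)).max() < 1e-8
    assert np.abs(X.T @ Gt).max() < 1e-8


def test_residualize_annihilates_covariate_span(rng):
    X = rng.standard_normal((50, 2))
    g = 0.3 + X @ [1.0, -2.0]
    col = residualize_genotypes(g[:, None], X)
    assert np.abs(col).max() < 1e-10


def test_statistic_direct_evaluation():
    r = np.array([0.5, -0.5, 0.5, -0.5])
    gt = np.array([[1.0], [-1.0], [1.0], [-1.0]])
    assert skat_statistic(r, np.zeros(4), gt, np.array([1.0])) == pytest.approx(2.0)
    assert skat_statistic(r, r, gt, np.array([1.0])) == 0.0
    t1 = skat_statistic(r, np.zeros(4), gt, np.array([1.0]))
    t2 = skat_statistic(r, np.zeros(4), gt, np.array([2.0]))
    assert t2 == pytest.approx(2 * t1)


def test_rank_one_spectrum_closed_form():
    gt = np.array([[1.0], [-1.0]])
    spec = mixture_eigenvalues(gt, np.array([1.0]), np.array([0.25, 0.25]))
    assert spec.lambdas.size == 1
    assert spec.lambdas[0] == pytest.approx(0.25)


def test_moment_formulas_from_eigenvalues():
    spec = MixtureSpectrum.from_lambdas(np.array([2.0, 1.0]))
    assert spec.ET == pytest.approx(3.0)
    assert spec.VarT == pytest.approx(10.0)
    assert spec.M3 == pytest.approx(72.0)
    assert spec.xi == pytest.approx(72.0 / 10**1.5, rel=1e-12)


def test_small_n_full_eigendecomposition_oracle(rng):
    """M x M route agrees with the brute-force n x n spectrum."""
    n, M = 40, 6
    Gt = residualize_genotypes(rng.integers(0, 3, (n, M)).astype(float), None)
    w = rng.uniform(0.5, 2.0, M)
    v = rng.uniform(0.1, 0.4, n)
    spec = mixture_eigenvalues(Gt, w, v)
    big = 0.5 * np.sqrt(v)[:, None] * (Gt @ np.diag(w) @ Gt.T) * np.sqrt(v)[None, :]
    lam_full = np.sort(np.linalg.eigvalsh(big))[::-1][: spec.lambdas.size]
    np.testing.assert_allclose(spec.lambdas, lam_full, atol=1e-8)


def test_pearson3_parameter_matching():
    xi = 2 * np.sqrt(2)
    par = pearson3_params(xi)
    assert par.scale_a == pytest.approx(np.sqrt(2))
    assert par.shape_b == pytest.approx(0.5)
    assert par.location_c == pytest.approx(-1 / np.sqrt(2))


@given(st.floats(0.05, 10.0))
@settings(max_examples=50, deadline=None)
def test_pearson3_unit_moment_constraints(xi):
    par = pearson3_params(xi)
    assert par.shape_b * par.scale_a**2 == pytest.approx(1.0)
    assert par.location_c + par.shape_b * par.scale_a == pytest.approx(0.0)


def test_pearson3_normal_limit():
    """As skewness vanishes the matched law approaches a standard normal."""
    spec = MixtureSpectrum.from_lambdas(np.full(100_000, 1.0))
    T = spec.ET + 1.96 * np.sqrt(spec.VarT)
    assert pearson3_pvalue(T, spec) == pytest.approx(0.025, abs=2e-3)


def test_single_eigenvalue_is_exact_chi_square():
    for lam in (1.0, 3.7):
        spec = MixtureSpectrum.from_lambdas(np.array([lam]))
        p = pearson3_pvalue(lam * 3.8415, spec)
        assert p == pytest.approx(stats.chi2.sf(3.8415, 1), abs=1e-9)
        assert p == pytest.approx(0.05, abs=1e-4)


def test_pvalue_invariant_under_weight_rescaling(small_dataset):
    _, G, X, y, _ = small_dataset
    base = pom_skat_test(y, X, G)
    w = beta_weights(G.maf)
    scaled = KernelWeights(7.0 * w.weights, w.maf_used, w.spec)
    res = pom_skat_test(y, X, G, weight_spec=scaled)
    assert res.p_value == pytest.approx(base.p_value, abs=1e-10)
    assert res.statistic_T == pytest.approx(7 * base.statistic_T, rel=1e-10)


def test_pvalue_invariant_under_joint_permutations(small_dataset, rng):
    _, G, X, y, _ = small_dataset
    base = pom_skat_test(y, X, G)
    # SNP column shuffle
    cols = rng.permutation(G.M)
    Gc = GenotypeMatrix.from_dosages(G.dosages[:, cols],
                                     [G.snp_ids[c] for c in cols])
    assert pom_skat_test(y, X, Gc).p_value == pytest.approx(base.p_value,
                                                            abs=1e-9)
    # joint subject row shuffle
    rows = rng.permutation(G.n)
    Gr = GenotypeMatrix.from_dosages(G.dosages[rows], G.snp_ids)
    assert pom_skat_test(y[rows], X[rows], Gr).p_value == pytest.approx(
        base.p_value, abs=1e-9)


def test_coding_flip_invariance(small_dataset):
    """Swapping which allele is counted leaves the p-value unchanged."""
    _, G, X, y, _ = small_dataset
    flipped = G.dosages.copy()
    flipped[:, ::2] = 2 - flipped[:, ::2]
    Gf = GenotypeMatrix.from_dosages(flipped, G.snp_ids)
    assert pom_skat_test(y, X, Gf).p_value == pytest.approx(
        pom_skat_test(y, X, G).p_value, abs=1e-9)


def test_binary_phenotype_reduction(small_dataset):
    """J=2 input runs the identical machinery on the logistic null."""
    _, G, X, y, _ = small_dataset
    yb = (y > 0).astype(int)
    res = pom_skat_test(yb, X, G)
    null = fit_null(yb, X)
    Gt = residualize_genotypes(G, X)
    w = beta_weights(G.maf)
    T = skat_statistic(yb, null.mu_hat, Gt, w)
    assert res.J == 2
    assert res.statistic_T == pytest.approx(T, rel=1e-12)
    assert np.allclose(null.var_hat, null.mu_hat * (1 - null.mu_hat))


def test_degenerate_snps_dropped_with_accounting(small_dataset):
    _, G, X, y, _ = small_dataset
    dos = G.dosages.copy()
    dos[:, 0] = 0                              # monomorphic column
    Gm = GenotypeMatrix(dos, G.snp_ids, np.minimum(
        dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2))
    res = pom_skat_test(y, X, Gm)
    assert res.M_dropped == 1 and res.M_used == G.M - 1
    assert res.dropped_snps == (G.snp_ids[0],)


def test_permutation_pvalue_formula_and_degenerate_input(small_dataset):
    _, G, X, y, _ = small_dataset
    with pytest.raises(ValueError, match="H must be"):
        permutation_pvalue(y, X, G, H=0)
    with pytest.raises(ValueError, match="no variation"):
        permutation_pvalue(np.zeros_like(y), X, G, H=10)
    p = permutation_pvalue(y, X, G, H=99, seed=1)
    assert p * 100 == pytest.approx(round(p * 100))  # granularity 1/(H+1)
    assert 0 < p <= 1


def test_montecarlo_mixture_oracle(rng):
    """Pearson III tail matches 10^6 draws of the chi-square mixture."""
    lam = rng.uniform(0.5, 1.5, 10)
    spec = MixtureSpectrum.from_lambdas(lam)
    draws = rng.chisquare(1, (1_000_000, 10)) @ lam
    for q in (0.5, 0.9, 0.95, 0.99):
        T = np.quantile(draws, q)
        assert pearson3_pvalue(T, spec) == pytest.approx(1 - q, abs=5e-3)
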