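"""PLS correlation: standardization, SVD, permutations, bootstrap, scores."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from longdti.pls import (
    bootstrap_weights,
    cross_correlation,
    latent_scores,
    permutation_test,
    pls_correlation,
    svd_components,
    zscore_columns,
)


def _random_blocks(seed, n=60, p=12, q=5):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, p)), rng.normal(size=(n, q))


def _planted_blocks(seed, n=200, p=12, q=5, effect=1.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=q)
    u /= np.linalg.norm(u)
    v = rng.normal(size=p)
    v /= np.linalg.norm(v)
    score = rng.normal(size=n)
    X = rng.normal(size=(n, p)) + effect * np.outer(score, v)
    Y = rng.normal(size=(n, q)) + effect * np.outer(score, u)
    return X, Y, u, v


# --- z-scoring -------------------------------------------------------------

def test_zscore_binary_column_worked_example():
    z = zscore_columns(np.array([[0.0], [1.0], [0.0], [1.0]]))
    np.testing.assert_allclose(z[:, 0], [-0.866, 0.866, -0.866, 0.866], atol=5e-4)


def test_zscore_moments_and_idempotence():
    X, _ = _random_blocks(0)
    z = zscore_columns(X)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)
    np.testing.assert_allclose(zscore_columns(z), z, atol=1e-12)


def test_zscore_constant_column_names_offender():
    X = np.ones((5, 2))
    X[:, 0] = np.arange(5)
    with pytest.raises(ValueError, match="col1"):
        zscore_columns(X)


# --- cross-correlation -----------------------------------------------------

def test_cross_correlation_matches_pairwise_pearson():
    X, Y = _random_blocks(1)
    R = cross_correlation(zscore_columns(X), zscore_columns(Y))
    for j in range(Y.shape[1]):
        for k in range(X.shape[1]):
            assert R[j, k] == pytest.approx(pearsonr(Y[:, j], X[:, k])[0], abs=1e-10)


def test_cross_correlation_self_column_is_one():
    X, _ = _random_blocks(2)
    Y = X[:, :3]
    R = cross_correlation(zscore_columns(X), zscore_columns(Y))
    np.testing.assert_allclose(np.diag(R[:, :3]), 1.0, atol=1e-12)


def test_cross_correlation_row_mismatch():
    with pytest.raises(ValueError):
        cross_correlation(np.zeros((5, 2)), np.zeros((6, 2)))


# --- SVD -------------------------------------------------------------------

def test_svd_rank_one_exact():
    u = np.array([0.6, -0.8])
    v = np.array([1.0, 2.0, -2.0]) / 3.0
    comps = svd_components(0.9 * np.outer(u, v))
    s = [c.singular_value for c in comps]
    assert s[0] == pytest.approx(0.9, abs=1e-12)
    assert all(x == pytest.approx(0.0, abs=1e-12) for x in s[1:])


def test_svd_diagonal_case():
    comps = svd_components(np.array([[1.0, 0.0], [0.0, 0.5]]))
    assert [c.singular_value for c in comps] == pytest.approx([1.0, 0.5])


def test_svd_energy_conservation_and_reconstruction():
    X, Y = _random_blocks(3)
    R = cross_correlation(zscore_columns(X), zscore_columns(Y))
    comps = svd_components(R)
    s2 = sum(c.singular_value**2 for c in comps)
    assert s2 == pytest.approx(np.linalg.norm(R, "fro") ** 2, abs=1e-10)
    assert sum(c.explained_correlation for c in comps) == pytest.approx(1.0, abs=1e-12)
    recon = sum(
        c.singular_value * np.outer(c.behavior_saliences, c.brain_saliences)
        for c in comps
    )
    np.testing.assert_allclose(recon, R, atol=1e-10)


def test_svd_sign_convention():
    X, Y = _random_blocks(4)
    comps = svd_components(cross_correlation(zscore_columns(X), zscore_columns(Y)))
    for c in comps:
        lead = np.argmax(np.abs(c.behavior_saliences))
        assert c.behavior_saliences[lead] > 0


def test_first_component_maximizes_bilinear_form():
    """No random unit pair may exceed s1 = max u^T R v (SVD optimality)."""
    rng = np.random.default_rng(5)
    R = rng.normal(size=(5, 5)) * 0.2
    comps = svd_components(R)
    s1 = comps[0].singular_value
    u0, v0 = comps[0].behavior_saliences, comps[0].brain_saliences
    assert u0 @ R @ v0 == pytest.approx(s1, abs=1e-10)
    U = rng.normal(size=(2000, 5))
    V = rng.normal(size=(2000, 5))
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    probes = np.einsum("ij,jk,ik->i", U, R, V)
    assert probes.max() <= s1 + 1e-9


# --- permutation test ------------------------------------------------------

def test_permutation_p_lower_bound_and_determinism():
    X, Y = _random_blocks(6)
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    p1 = permutation_test(Xz, Yz, n_perm=200, seed=42)
    p2 = permutation_test(Xz, Yz, n_perm=200, seed=42)
    np.testing.assert_array_equal(p1, p2)
    assert np.all(p1 >= 1.0 / 201.0)
    assert np.all(p1 <= 1.0)


def test_permutation_detects_planted_association():
    X, Y, _, _ = _planted_blocks(7, effect=1.0)
    p = permutation_test(zscore_columns(X), zscore_columns(Y), n_perm=200, seed=0)
    assert p[0] == pytest.approx(1.0 / 201.0)


def test_joint_row_permutation_preserves_p_values():
    """Permuting X and Y rows with the SAME permutation preserves the
    association: the observed statistic is identical and the p-values agree
    within Monte-Carlo resolution."""
    X, Y, _, _ = _planted_blocks(8, n=80, effect=0.4)
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    perm = np.random.default_rng(1).permutation(X.shape[0])
    s1 = np.linalg.svd(cross_correlation(Xz, Yz), compute_uv=False)
    s2 = np.linalg.svd(cross_correlation(Xz[perm], Yz[perm]), compute_uv=False)
    np.testing.assert_allclose(s1, s2, atol=1e-12)
    p1 = permutation_test(Xz, Yz, n_perm=500, seed=9)
    p2 = permutation_test(Xz[perm], Yz[perm], n_perm=500, seed=9)
    assert np.max(np.abs(p1 - p2)) <= 0.1  # ~3 binomial SDs at n_perm=500


def test_permutation_requires_enough_rows():
    with pytest.raises(ValueError):
        permutation_test(np.zeros((3, 2)), np.zeros((3, 2)), n_perm=100)


# --- bootstrap -------------------------------------------------------------

def test_bootstrap_determinism_and_stability_flags():
    X, Y, _, _ = _planted_blocks(10, effect=1.5)
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    comps = svd_components(cross_correlation(Xz, Yz))
    b1 = bootstrap_weights(Xz, Yz, comps, n_boot=150, seed=3)
    b2 = bootstrap_weights(Xz, Yz, comps, n_boot=150, seed=3)
    np.testing.assert_array_equal(b1.behavior_score, b2.behavior_score)
    assert b1.behavior_stable.shape == (len(comps), Y.shape[1])
    assert np.all(b1.behavior_sd >= 0)
    assert np.all((np.abs(b1.brain_score) > 1.96) == b1.brain_stable)


def test_bootstrap_strong_structure_all_weights_stable():
    """With a dominant noiseless rank-1 structure every truly loaded weight
    must be flagged robust."""
    rng = np.random.default_rng(11)
    n = 100
    score = rng.normal(size=n)
    u = np.array([3.0, -2.0, 1.0, 0.5, -0.5])
    u /= np.linalg.norm(u)
    v = rng.normal(size=8)
    v /= np.linalg.norm(v)
    X = np.outer(score, v) + 0.01 * rng.normal(size=(n, 8))
    Y = np.outer(score, u) + 0.01 * rng.normal(size=(n, 5))
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    comps = svd_components(cross_correlation(Xz, Yz))
    boot = bootstrap_weights(Xz, Yz, comps, n_boot=200, seed=4)
    assert np.all(np.abs(boot.behavior_score[0]) > 1.96)
    assert np.all(np.abs(boot.brain_score[0]) > 1.96)


def test_bootstrap_redraws_constant_risk_columns():
    """Rare binary columns force degenerate resamples that must be redrawn,
    not used."""
    rng = np.random.default_rng(12)
    n = 25
    Y = rng.integers(0, 2, size=(n, 3)).astype(float)
    Y[:, 0] = 0.0
    Y[:2, 0] = 1.0  # rare factor: constant in many resamples
    X = rng.normal(size=(n, 6))
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    comps = svd_components(cross_correlation(Xz, Yz))
    boot = bootstrap_weights(Xz, Yz, comps, n_boot=150, seed=5)
    assert boot.n_redrawn > 0
    assert np.all(np.isfinite(boot.behavior_score))


# --- latent scores ---------------------------------------------------------

def test_zero_brain_row_gives_zero_brain_scores():
    X, Y = _random_blocks(13)
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    Xz[0, :] = 0.0
    comps = svd_components(cross_correlation(Xz, Yz))
    ls = latent_scores(Xz, Yz, comps)
    np.testing.assert_allclose(ls.L_X[0], 0.0, atol=1e-12)


def test_latent_score_covariance_identity():
    """(n-1)^-1 L_X[:,k]^T L_Y[:,k] = s_k, the algebraic identity
    u^T R v = s applied to the projections."""
    X, Y = _random_blocks(14)
    Xz, Yz = zscore_columns(X), zscore_columns(Y)
    comps = svd_components(cross_correlation(Xz, Yz))
    ls = latent_scores(Xz, Yz, comps)
    n = X.shape[0]
    for k, c in enumerate(comps):
        cov = ls.L_X[:, k] @ ls.L_Y[:, k] / (n - 1)
        assert cov == pytest.approx(c.singular_value, abs=1e-10)
    assert np.all(np.abs(ls.r) <= 1.0 + 1e-12)


# --- end-to-end ------------------------------------------------------------

def test_pls_correlation_end_to_end_recovers_planted_weights():
    X, Y, u, v = _planted_blocks(15, n=300, effect=1.0)
    res = pls_correlation(X, Y, n_perm=200, n_boot=150, seed=8)
    assert res.perm_p[0] < 0.05
    c1 = res.components[0]
    ru = np.corrcoef(c1.behavior_saliences, u)[0, 1]
    rv = np.corrcoef(c1.brain_saliences, v)[0, 1]
    assert abs(ru) >= 0.9 and abs(rv) >= 0.9
    # explained fractions sum to one over all components
    assert sum(c.explained_correlation for c in res.components) == pytest.approx(1.0)
    # component-1 latent correlation positive under the sign convention
    assert res.scores.r[0] > 0


def test_explained_fraction_invariant_to_x_column_order():
    X, Y = _random_blocks(16)
    res1 = pls_correlation(X, Y, n_perm=100, n_boot=100, seed=1)
    perm = np.random.default_rng(2).permutation(X.shape[1])
    res2 = pls_correlation(X[:, perm], Y, n_perm=100, n_boot=100, seed=1)
    np.testing.assert_allclose(
        [c.explained_correlation for c in res1.components],
        [c.explained_correlation for c in res2.components],
        atol=1e-10,
    )
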