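import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imagecca.fixtures import planted_cca_matrices
from imagecca.sparse_cca import (CCAConfig, compute_pve, fit_sparse_cca,
                                 l1_bounded_unit_vector, permutation_validation,
                                 pmd_rank1, soft_threshold, tune_hyperparameters)


def standardize(M):
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


class TestSoftThreshold:
    def test_definition_example(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([2.0, -1.0, 0.5]), 1.0), [1.0, 0.0, 0.0])

    def test_zero_delta_is_identity(self):
        x = np.array([0.3, -2.0, 5.0])
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_matches_lasso_prox_grid_oracle(self):
        """S(x, d) minimizes 0.5 (y - x)^2 + d |y| per coordinate."""
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 3, size=5)
        delta = 0.7
        grid = np.linspace(-4, 4, 160001)
        for xi, si in zip(x, soft_threshold(x, delta)):
            obj = 0.5 * (grid - xi) ** 2 + delta * np.abs(grid)
            assert abs(grid[np.argmin(obj)] - si) < 1e-4

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20),
           st.floats(0, 5))
    def test_shrinks_toward_zero(self, xs, delta):
        x = np.array(xs)
        s = soft_threshold(x, delta)
        assert np.all(np.abs(s) <= np.abs(x) + 1e-12)
        assert np.all(s * x >= 0)


class TestL1BoundedUnitVector:
    def test_loose_bound_plain_normalization(self):
        a = np.array([3.0, -4.0, 1.0, 0.5])
        out = l1_bounded_unit_vector(a, np.sqrt(4))
        np.testing.assert_allclose(out, a / np.linalg.norm(a), atol=1e-9)

    def test_tight_bound_single_spike_lowest_index_tie(self):
        a = np.array([2.0, -2.0, 1.0])
        out = l1_bounded_unit_vector(a, 1.0)
        np.testing.assert_array_equal(out, [1.0, 0.0, 0.0])

    def test_active_constraint_hits_bound_vs_grid_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(30)
        out = l1_bounded_unit_vector(a, 2.0)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(out).sum() == pytest.approx(2.0, abs=1e-6)
        # independent fine delta-grid search
        best = None
        for delta in np.linspace(0, np.abs(a).max(), 20000):
            s = soft_threshold(a, delta)
            norm = np.linalg.norm(s)
            if norm > 0 and np.abs(s / norm).sum() <= 2.0 + 1e-9:
                best = s / norm
                break
        np.testing.assert_allclose(np.abs(out).sum(), np.abs(best).sum(),
                                   atol=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            l1_bounded_unit_vector(np.zeros(4), 1.5)

    def test_closed_form_matches_bisection_oracle(self):
        """The segment-wise closed-form threshold agrees with a plain
        interval bisection, including vectors with tied magnitudes."""
        from imagecca.sparse_cca import _delta_bisect

        rng = np.random.default_rng(3)
        for trial in range(300):
            d = int(rng.integers(2, 60))
            a = rng.standard_normal(d) * rng.uniform(0.1, 10)
            if trial % 5 == 0:
                a[: d // 2] = a[0]  # tied block
            c = float(rng.uniform(1.0, np.sqrt(d)))
            out = l1_bounded_unit_vector(a, c)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)
            assert np.abs(out).sum() <= c + 1e-7
            abs_a = np.abs(a)
            delta = _delta_bisect(abs_a, c, 0.0, float(abs_a.max()))
            s = soft_threshold(a, delta)
            norm = np.linalg.norm(s)
            if norm == 0 or np.abs(s / norm).sum() > c + 1e-6:
                continue  # tied maxima: no threshold attains the bound
            np.testing.assert_allclose(out, s / norm, atol=1e-6)

    def test_tied_maxima_spread_over_floor_c_squared(self):
        """When the largest |a| values are tied no threshold can reach the
        bound; the returned vector spreads over the floor(c^2) leading
        coordinates instead."""
        a = np.array([2.0, -2.0, 2.0, 2.0, 0.5])
        out = l1_bounded_unit_vector(a, 1.8)  # floor(c^2) = 3 survivors
        expected = np.array([1.0, -1.0, 1.0, 0.0, 0.0]) / np.sqrt(3)
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestPMDRank1:
    def test_separable_unit_case(self):
        C = np.outer(np.eye(5)[0], np.eye(7)[1])
        u, v, d, conv = pmd_rank1(C, 1.0, 1.0)
        np.testing.assert_allclose(u, np.eye(5)[0], atol=1e-9)
        np.testing.assert_allclose(v, np.eye(7)[1], atol=1e-9)
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_loose_penalties_recover_leading_singular_pair(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            C = rng.standard_normal((20, 30))
            u, v, d, _ = pmd_rank1(C, np.sqrt(20), np.sqrt(30))
            U, s, Vt = np.linalg.svd(C)
            assert abs(u @ U[:, 0]) >= 0.999
            assert abs(v @ Vt[0]) >= 0.999
            assert d == pytest.approx(s[0], abs=1e-6)

    def test_objective_non_decreasing_over_iterations(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            C = rng.standard_normal((15, 12))
            trace = []
            pmd_rank1(C, 2.0, 2.0, objective_trace=trace)
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-10)

    def test_nonfinite_matrix_rejected(self):
        C = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            pmd_rank1(C, 1.0, 1.0)


class TestFitSparseCCA:
    def test_deflation_removes_rank_one_structure(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal(80)
        X = standardize(np.outer(t, rng.standard_normal(6))
                        + 1e-3 * rng.standard_normal((80, 6)))
        Z = standardize(np.outer(t, rng.standard_normal(5))
                        + 1e-3 * rng.standard_normal((80, 5)))
        fit = fit_sparse_cca(X, Z, CCAConfig(K=2, lambda_images=1.0,
                                             lambda_genes=1.0))
        assert fit.d[1] <= 1e-2 * fit.d[0]

    def test_dense_limit_matches_classical_diagonal_cca(self):
        """lambda = 1 on both sides: canonical correlation of (Xu, Zv)
        matches the SVD of the cross-correlation matrix."""
        rng = np.random.default_rng(5)
        F = rng.standard_normal((300, 1))
        X = standardize(F @ rng.standard_normal((1, 4))
                        + rng.standard_normal((300, 4)))
        Z = standardize(F @ rng.standard_normal((1, 3))
                        + rng.standard_normal((300, 3)))
        fit = fit_sparse_cca(X, Z, CCAConfig(K=1, lambda_images=1.0,
                                             lambda_genes=1.0))
        r_fit = np.corrcoef(fit.gene_scores[:, 0], fit.image_scores[:, 0])[0, 1]
        C = X.T @ Z / 299
        U, s, Vt = np.linalg.svd(C)
        r_oracle = np.corrcoef(X @ U[:, 0], Z @ Vt[0])[0, 1]
        assert abs(abs(r_fit) - abs(r_oracle)) <= 0.05

    def test_planted_sparse_pair_support_recovery(self):
        f1s = []
        for seed in range(5):
            X, Z, truth = planted_cca_matrices(200, 500, 100, 10, 5,
                                               signal=0.8, seed=seed)
            cfg = CCAConfig(K=1,
                            lambda_genes=np.sqrt(10) / np.sqrt(500),
                            lambda_images=np.sqrt(5) / np.sqrt(100))
            fit = fit_sparse_cca(standardize(X), standardize(Z), cfg)
            est = set(np.nonzero(fit.U[:, 0])[0])
            true = set(truth["gene_support"][0])
            f1s.append(2 * len(est & true) / (len(est) + len(true)))
        assert np.mean(f1s) >= 0.7  # per-seed; the averaged bar is checked at n=20

    def test_sparsity_monotone_in_gene_penalty(self):
        X, Z, _ = planted_cca_matrices(150, 200, 50, 10, 5, signal=0.8, seed=9)
        Xs, Zs = standardize(X), standardize(Z)
        nnz = []
        for lam in (0.4, 0.2, 0.1):
            fit = fit_sparse_cca(Xs, Zs, CCAConfig(K=1, lambda_images=0.4,
                                                   lambda_genes=lam))
            nnz.append(int((fit.U[:, 0] != 0).sum()))
        assert nnz[0] >= nnz[1] >= nnz[2]

    def test_sample_misalignment_rejected(self):
        from imagecca.features import EmbeddingMatrix, ExpressionMatrix
        X = ExpressionMatrix(["a", "b", "c"], ["g1", "g2"], np.zeros((3, 2)))
        Z = EmbeddingMatrix(["a", "b", "d"], np.zeros((3, 2)))
        with pytest.raises(ValueError, match="d"):
            fit_sparse_cca(X, Z, CCAConfig(K=1))

    def test_sign_convention_strongest_feature_positive(self):
        X, Z, _ = planted_cca_matrices(100, 50, 20, 5, 3, signal=0.8, seed=11)
        fit = fit_sparse_cca(standardize(X), standardize(Z),
                             CCAConfig(K=3, lambda_images=0.8, lambda_genes=0.8))
        for k in range(3):
            v = fit.V[:, k]
            if np.any(v):
                assert v[np.argmax(np.abs(v))] > 0


class TestPVE:
    def test_single_component_is_one(self):
        np.testing.assert_allclose(compute_pve(np.array([3.0])), [1.0])

    def test_arithmetic_example(self):
        np.testing.assert_allclose(compute_pve(np.array([2.0, 1.0])), [0.8, 0.2])

    def test_sums_to_one(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0.1, 5.0, size=20)
        assert compute_pve(d).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_pve(np.zeros(3))


class TestTuning:
    def test_noiseless_linear_map_recovered(self):
        rng = np.random.default_rng(7)
        F = rng.standard_normal((100, 3))
        X = standardize(F @ rng.standard_normal((3, 40)))
        Z = standardize(F @ rng.standard_normal((3, 25)))
        tab = tune_hyperparameters(X, Z, [(1.0, 1.0)], seed=0, K=3)
        assert tab.corr_X.iloc[0] >= 0.95
        assert tab.corr_Z.iloc[0] >= 0.95

    def test_permuted_samples_destroy_signal(self):
        rng = np.random.default_rng(8)
        F = rng.standard_normal((200, 3))
        X = standardize(F @ rng.standard_normal((3, 40))
                        + rng.standard_normal((200, 40)))
        Z = standardize(F @ rng.standard_normal((3, 25))
                        + rng.standard_normal((200, 25)))[rng.permutation(200)]
        tab = tune_hyperparameters(X, Z, [(1.0, 1.0)], seed=0, K=3)
        assert abs(tab.corr_X.iloc[0]) < 0.1
        assert abs(tab.corr_Z.iloc[0]) < 0.1

    def test_single_cell_grid_contract(self):
        rng = np.random.default_rng(9)
        X = standardize(rng.standard_normal((40, 10)))
        Z = standardize(rng.standard_normal((40, 8)))
        tab = tune_hyperparameters(X, Z, [(0.5, 0.5)], seed=1, K=2)
        assert len(tab) == 1
        assert np.isfinite(tab[["corr_X", "corr_Z"]].to_numpy()).all()

    def test_degenerate_holdout_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            tune_hyperparameters(X, X, [(1.0, 1.0)], holdout_fraction=0.1)


class TestPermutationValidation:
    def test_single_permutation_support(self):
        rng = np.random.default_rng(10)
        X = standardize(rng.standard_normal((30, 8)))
        Z = standardize(rng.standard_normal((30, 6)))
        _, _, p = permutation_validation(X, Z, CCAConfig(K=2), n_perms=1,
                                         k_top=2, seed=0)
        assert p in (0.5, 1.0)

    def test_planted_signal_minimal_p(self):
        X, Z, _ = planted_cca_matrices(200, 100, 50, 10, 5, signal=0.8, seed=0)
        cfg = CCAConfig(K=10, lambda_images=0.3, lambda_genes=0.3)
        _, null, p = permutation_validation(standardize(X), standardize(Z),
                                            cfg, n_perms=20, k_top=10, seed=1)
        assert p == pytest.approx(1 / 21)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            permutation_validation(np.zeros((2, 3)), np.zeros((2, 3)),
                                   CCAConfig(K=1), n_perms=5)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_lambda_out_of_range(self, bad):
        with pytest.raises(ValueError):
            CCAConfig(lambda_images=bad)
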