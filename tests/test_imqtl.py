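import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import rankdata

from imagecca.imqtl import (GenotypeTable, association_scan, bh_fdr,
                            build_test_set, quantile_normalize_features,
                            standardize_features)
from imagecca.sparse_cca import CCAConfig, CCADecomposition


def mock_decomp(U, V, sample_ids, gene_ids):
    U, V = np.asarray(U, float), np.asarray(V, float)
    K = U.shape[1]
    n = len(sample_ids)
    return CCADecomposition(
        U=U, V=V, d=np.ones(K), gene_scores=np.zeros((n, K)),
        image_scores=np.zeros((n, K)), pve=np.ones(K) / K,
        config=CCAConfig(K=K), gene_ids=list(gene_ids),
        sample_ids=list(sample_ids))


class TestQuantileNormalization:
    def test_rank_preserving_within_feature(self):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((100, 5))
        out = quantile_normalize_features(F)
        for j in range(5):
            rho = stats.spearmanr(F[:, j], out[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_features_share_the_pooled_output_scale(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((200, 4))
        F[:, 0] *= 1000.0  # heavy-scale feature
        out = quantile_normalize_features(F)
        # every untied feature maps onto the same pooled quantile values
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, j]),
                                       atol=1e-9)

    def test_hand_computed_small_matrix(self):
        F = np.array([[1.0, 10.0],
                      [2.0, 40.0],
                      [3.0, 20.0],
                      [4.0, 30.0]])
        out = quantile_normalize_features(F)
        pooled = np.sort(F.ravel())
        fracs = (rankdata(F[:, 1]) - 0.5) / 4  # [0.125, 0.875, 0.375, 0.625]
        expected = np.quantile(pooled, fracs)
        np.testing.assert_allclose(out[:, 1], expected, atol=1e-12)
        np.testing.assert_allclose(out[:, 0], np.quantile(pooled,
                                                          [0.125, 0.375, 0.625, 0.875]),
                                   atol=1e-12)

    def test_constant_feature_maps_to_pooled_median(self):
        F = np.column_stack([np.full(10, 7.0),
                             np.arange(10.0)])
        with pytest.warns(UserWarning):
            out = quantile_normalize_features(F)
        assert np.allclose(out[:, 0], np.quantile(np.sort(F.ravel()), 0.5))

    def test_zscore_alternative_unit_variance(self):
        rng = np.random.default_rng(2)
        F = rng.standard_normal((50, 3)) * [1, 10, 100]
        out = standardize_features(F)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestGenotypeTable:
    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            GenotypeTable(["s1"], ["a", "b"], np.array([[0.0], [3.0]]))

    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError):
            GenotypeTable(["s1"], ["a", "a"], np.zeros((2, 1)))

    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame([[0, 1, 2], [2, 1, 0]], index=["snp1", "snp2"],
                          columns=["a", "b", "c"], dtype=float)
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t")
        G = GenotypeTable.from_tsv(path)
        np.testing.assert_array_equal(G.dosages, df.to_numpy().T)


class TestBuildTestSet:
    def setup_method(self):
        self.samples = [f"S{i}" for i in range(60)]
        self.genes = [f"g{i}" for i in range(6)]
        self.labels = pd.Series(["t0"] * 30 + ["t1"] * 30, index=self.samples)
        self.expr = pd.DataFrame(np.ones((6, 60)), index=self.genes,
                                 columns=self.samples)

    def test_zero_weight_component_contributes_no_pairs(self):
        U = np.zeros((6, 1))
        V = np.zeros((3, 1)); V[0] = 1
        d = mock_decomp(U, V, self.samples, self.genes)
        eqtl = pd.DataFrame({"snp_id": ["s1"], "gene_id": ["g0"],
                             "tissue": ["t0"]})
        with pytest.warns(UserWarning):
            pairs = build_test_set(d, eqtl, self.expr, self.labels)
        assert pairs.empty

    def test_planted_chain_appears_exactly(self):
        U = np.zeros((6, 2)); U[0, 0] = 1.0
        V = np.zeros((3, 2)); V[1, 0] = 1.0
        d = mock_decomp(U, V, self.samples, self.genes)
        eqtl = pd.DataFrame({
            "snp_id": ["snpA", "snpB", "snpC"],
            "gene_id": ["g0", "g0", "g5"],          # g5 has zero weight
            "tissue": ["t0", "t9", "t0"],           # t9 has no samples
        })
        pairs = build_test_set(d, eqtl, self.expr, self.labels)
        assert pairs.to_records(index=False).tolist() == [
            ("snpA", 1, "t0", "g0", 0)]

    def test_small_tissue_excluded(self):
        U = np.zeros((6, 1)); U[0, 0] = 1.0
        V = np.zeros((3, 1)); V[0, 0] = 1.0
        d = mock_decomp(U, V, self.samples, self.genes)
        labels = pd.Series(["t0"] * 19 + ["t1"] * 41, index=self.samples)
        eqtl = pd.DataFrame({"snp_id": ["s", "s"], "gene_id": ["g0", "g0"],
                             "tissue": ["t0", "t1"]})
        pairs = build_test_set(d, eqtl, self.expr, labels, min_samples=20)
        assert set(pairs.tissue) == {"t1"}

    def test_silent_gene_in_tissue_excluded(self):
        U = np.zeros((6, 1)); U[0, 0] = 1.0
        V = np.zeros((3, 1)); V[0, 0] = 1.0
        d = mock_decomp(U, V, self.samples, self.genes)
        expr = self.expr.copy()
        expr.loc["g0", self.labels == "t0"] = 0.0  # silent in t0
        eqtl = pd.DataFrame({"snp_id": ["s", "s"], "gene_id": ["g0", "g0"],
                             "tissue": ["t0", "t1"]})
        pairs = build_test_set(d, eqtl, expr, self.labels)
        assert set(pairs.tissue) == {"t1"}


class TestAssociationScan:
    def _scan_single(self, x, y, n=None):
        n = n or len(x)
        samples = [f"S{i}" for i in range(n)]
        G = GenotypeTable(["snp"], samples, np.asarray(x, float)[:, None])
        F = np.asarray(y, float)[:, None]
        pairs = pd.DataFrame({"snp_id": ["snp"], "feature_index": [0],
                              "tissue": ["t"], "gene_id": ["g"],
                              "component": [0]})
        labels = pd.Series(["t"] * n, index=samples)
        return association_scan(G, F, pairs, labels, sample_ids=samples,
                                min_samples=3)

    def test_closed_form_beta(self):
        res = self._scan_single([0, 1, 2, 0, 1, 2],
                                [0.1, 1.1, 2.1, -0.1, 0.9, 1.9])
        assert res.beta.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_fit_flagged_degenerate(self):
        x = np.array([0, 1, 2, 0, 1, 2], float)
        res = self._scan_single(x, x)
        assert bool(res.degenerate.iloc[0])
        assert res.p.iloc[0] <= np.finfo(float).tiny

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(300):
            x = rng.binomial(2, 0.4, 60).astype(float)
            if x.std() == 0:
                continue
            y = rng.standard_normal(60)
            ps.append(self._scan_single(x, y).p.iloc[0])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_beta_negates_under_dosage_recoding(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(2, 0.3, 80).astype(float)
        y = 0.4 * x + rng.standard_normal(80)
        res1 = self._scan_single(x, y)
        res2 = self._scan_single(2.0 - x, y)
        assert res2.beta.iloc[0] == pytest.approx(-res1.beta.iloc[0], rel=1e-12)
        assert res2.p.iloc[0] == pytest.approx(res1.p.iloc[0], rel=1e-9)

    def test_missing_dosages_dropped_pairwise(self):
        x = np.array([0, 1, 2, np.nan, 1, 2, 0, 1], float)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(8)
        res = self._scan_single(x, y)
        assert res.n_used.iloc[0] == 7

    def test_zero_variance_genotype_skipped(self):
        res = self._scan_single([1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6.0])
        assert res.empty

    def test_results_invariant_to_pair_order(self):
        rng = np.random.default_rng(6)
        n = 40
        samples = [f"S{i}" for i in range(n)]
        G = GenotypeTable(["a", "b"], samples,
                          rng.binomial(2, 0.4, (n, 2)).astype(float))
        F = rng.standard_normal((n, 2))
        labels = pd.Series(["t"] * n, index=samples)
        pairs = pd.DataFrame({"snp_id": ["a", "b"], "feature_index": [0, 1],
                              "tissue": ["t", "t"], "gene_id": ["g", "h"],
                              "component": [0, 0]})
        r1 = association_scan(G, F, pairs, labels, sample_ids=samples,
                              min_samples=3)
        r2 = association_scan(G, F, pairs.iloc[::-1], labels,
                              sample_ids=samples, min_samples=3)
        m1 = r1.set_index("snp_id")[["beta", "p", "q_fdr"]].sort_index()
        m2 = r2.set_index("snp_id")[["beta", "p", "q_fdr"]].sort_index()
        pd.testing.assert_frame_equal(m1, m2)


class TestBH:
    def test_step_up_hand_example(self):
        q, disc = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), 0.1)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        assert disc.all()

    def test_single_p_equals_q(self):
        q, _ = bh_fdr(np.array([0.037]))
        assert q[0] == pytest.approx(0.037)

    def test_empty_input(self):
        q, disc = bh_fdr(np.array([]))
        assert q.size == 0 and disc.size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.2]))
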