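import numpy as np
import pytest

from lungcad.fusion import (CcaModel, FeatureBlock, cca_fit, fuse, pca_fit,
                            pca_transform, select_pairs)
from lungcad.synthetic import FeatureGenSpec, gen_feature_pair


class TestPca:
    def test_rank_one_data_explained_by_first_component(self, rng):
        t = rng.normal(size=100)
        x = np.column_stack([np.zeros(100), t, 2 * t])
        model = pca_fit(FeatureBlock(x))
        assert model.cumulative_contribution[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_contributions_near_uniform(self, rng):
        x = rng.normal(size=(20000, 4))
        model = pca_fit(FeatureBlock(x))
        ratios = np.diff(np.r_[0.0, model.cumulative_contribution])
        np.testing.assert_allclose(ratios, 0.25, atol=0.05)

    def test_full_rank_roundtrip(self, rng):
        x = rng.normal(size=(50, 6))
        model = pca_fit(FeatureBlock(x))
        scores = pca_transform(model, x, 6).matrix
        recon = scores @ model.components[:, :6].T + model.mean
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_score_variance_equals_eigenvalue(self, rng):
        x = rng.normal(size=(300, 5)) * np.array([3.0, 2.0, 1.0, 0.5, 0.1])
        model = pca_fit(FeatureBlock(x))
        scores = pca_transform(model, x, 5).matrix
        np.testing.assert_allclose(scores.var(axis=0, ddof=1), model.eigenvalues,
                                   rtol=1e-8)

    def test_spectrum_invariants(self, rng):
        model = pca_fit(FeatureBlock(rng.normal(size=(40, 8))))
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= -1e-12)
        assert np.all(np.diff(model.cumulative_contribution) >= -1e-12)
        assert model.cumulative_contribution[-1] == pytest.approx(1.0, abs=1e-8)
        gram = model.components.T @ model.components
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_degenerate_and_bad_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(FeatureBlock(np.ones((10, 3))))
        model = pca_fit(FeatureBlock(rng.normal(size=(10, 3))))
        with pytest.raises(ValueError):
            pca_transform(model, rng.normal(size=(5, 3)), 0)
        with pytest.raises(ValueError):
            pca_transform(model, rng.normal(size=(5, 3)), 99)


class TestCca:
    def test_identical_blocks_fully_correlated(self, rng):
        x = rng.normal(size=(200, 10))
        model = cca_fit(FeatureBlock(x), FeatureBlock(x.copy()))
        np.testing.assert_allclose(model.rho, 1.0, atol=1e-6)

    def test_independent_blocks_near_zero(self, rng):
        m = rng.normal(size=(5000, 5))
        n = rng.normal(size=(5000, 5))
        model = cca_fit(FeatureBlock(m), FeatureBlock(n))
        assert np.all(model.rho < 0.1)

    def test_planted_correlations_recovered(self):
        spec = FeatureGenSpec(n=2000, p=20, q=20, delta=0.0, seed=3)
        m, n, _ = gen_feature_pair(spec)
        model = cca_fit(m, n)
        np.testing.assert_allclose(model.rho[:3], [0.9, 0.7, 0.5], atol=0.05)

    def test_invariance_under_invertible_transforms(self, rng):
        spec = FeatureGenSpec(n=500, p=8, q=6, s=2, rho=(0.8, 0.5), delta=0.0, seed=1)
        m, n, _ = gen_feature_pair(spec)
        base = cca_fit(m, n).rho
        a = rng.normal(size=(8, 8)) + 2 * np.eye(8)
        b = rng.normal(size=(6, 6)) + 2 * np.eye(6)
        transformed = cca_fit(FeatureBlock(m.matrix @ a), FeatureBlock(n.matrix @ b)).rho
        np.testing.assert_allclose(transformed, base, atol=1e-6)

    def test_variates_unit_variance_and_uncorrelated(self, rng):
        spec = FeatureGenSpec(n=800, p=6, q=6, s=2, rho=(0.8, 0.5), delta=0.0, seed=2)
        m, n, _ = gen_feature_pair(spec)
        model = cca_fit(m, n)
        u = (m.matrix - model.mean_m) @ model.w_m
        np.testing.assert_allclose(u.var(axis=0, ddof=1), 1.0, atol=1e-8)
        corr = np.corrcoef(u, rowvar=False)
        np.testing.assert_allclose(corr, np.eye(u.shape[1]), atol=1e-6)

    def test_rho_sorted_and_bounded(self, rng):
        model = cca_fit(FeatureBlock(rng.normal(size=(100, 7))),
                        FeatureBlock(rng.normal(size=(100, 4))))
        assert np.all((model.rho >= 0) & (model.rho <= 1))
        assert np.all(np.diff(model.rho) <= 1e-12)

    def test_agrees_with_independent_cca_solver(self, rng):
        from sklearn.cross_decomposition import CCA as SklearnCCA
        spec = FeatureGenSpec(n=600, p=5, q=5, s=2, rho=(0.85, 0.6), delta=0.0, seed=4)
        m, n, _ = gen_feature_pair(spec)
        model = cca_fit(m, n)
        sk = SklearnCCA(n_components=2, max_iter=2000).fit(m.matrix, n.matrix)
        u, v = sk.transform(m.matrix, n.matrix)
        sk_rho = [abs(np.corrcoef(u[:, j], v[:, j])[0, 1]) for j in range(2)]
        np.testing.assert_allclose(model.rho[:2], sk_rho, atol=1e-4)

    def test_mismatched_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cca_fit(FeatureBlock(rng.normal(size=(10, 3))),
                    FeatureBlock(rng.normal(size=(12, 3))))


class TestSelectionAndFusion:
    @staticmethod
    def _model_with_rho(rho):
        k = len(rho)
        return CcaModel(w_m=np.eye(k), w_n=np.eye(k), rho=np.asarray(rho),
                        mean_m=np.zeros(k), mean_n=np.zeros(k))

    @pytest.mark.parametrize("rho_min,expected", [(0.8, 2), (0.0, 3), (1.01, 0)])
    def test_threshold_counts_inclusive(self, rho_min, expected):
        model = self._model_with_rho([0.95, 0.85, 0.75])
        assert select_pairs(model, rho_min) == expected

    def test_boundary_is_inclusive(self):
        assert select_pairs(self._model_with_rho([0.9, 0.8, 0.7]), 0.8) == 2

    @pytest.mark.parametrize("l1", [1, 3, 59])
    def test_concat_doubles_sum_dimension(self, rng, l1):
        n, p = 80, max(l1 + 5, 10)
        spec = FeatureGenSpec(n=n, p=p, q=p, s=min(3, l1), delta=0.0, seed=0,
                              rho=(0.9, 0.7, 0.5)[:min(3, l1)])
        m, nb, _ = gen_feature_pair(spec)
        model = cca_fit(m, nb)
        con = fuse(model, m, nb, mode="concat", n_pairs=l1)
        par = fuse(model, m, nb, mode="sum", n_pairs=l1)
        assert con.n_features == 2 * l1
        assert par.n_features == l1

    def test_sum_of_identical_blocks_doubles_projection(self, rng):
        x = rng.normal(size=(60, 5))
        block = FeatureBlock(x)
        model = cca_fit(block, FeatureBlock(x.copy()))
        fused = fuse(model, block, block, mode="sum", n_pairs=3)
        m_star = (x - model.mean_m) @ model.w_m[:, :3]
        np.testing.assert_allclose(fused.matrix, 2 * m_star, atol=1e-5)

    def test_concat_columns_are_stacked_variates(self, rng):
        spec = FeatureGenSpec(n=100, p=6, q=4, s=2, rho=(0.8, 0.6), delta=0.0, seed=5)
        m, n, _ = gen_feature_pair(spec)
        model = cca_fit(m, n)
        fused = fuse(model, m, n, mode="concat", n_pairs=2)
        m_star = (m.matrix - model.mean_m) @ model.w_m[:, :2]
        n_star = (n.matrix - model.mean_n) @ model.w_n[:, :2]
        np.testing.assert_allclose(fused.matrix, np.hstack([m_star, n_star]))

    def test_unset_pair_count_rejected(self, rng):
        x = rng.normal(size=(50, 4))
        model = cca_fit(FeatureBlock(x), FeatureBlock(rng.normal(size=(50, 4))))
        with pytest.raises(ValueError):
            fuse(model, FeatureBlock(x), FeatureBlock(x))


def test_feature_block_validation():
    with pytest.raises(ValueError):
        FeatureBlock(np.array([[np.nan, 1.0], [0.0, 1.0]]))
    with pytest.raises(ValueError):
        FeatureBlock(np.ones((1, 4)))
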