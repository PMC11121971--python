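"""Pretreatment, PCA, K-means, NIPALS PLS and LOO Q2 against oracles."""

import numpy as np
import pandas as pd
import pytest

from oligodeg.chemometrics import (
    DescriptorPretreater,
    PLSRegressorQ2,
    ScaledPCA,
    kmeans_cluster,
    loo_q2,
    pca_fit,
    pls_fit,
    pretreat,
    select_features,
)
from oligodeg.synthetic_data import PlantedPLSConfig, gen_pls_dataset


class TestPretreat:
    def test_drop_counts_mirror_input_composition(self):
        """126 columns, 9 constant, 6 ADME-named (disjoint) -> 111 kept."""
        rng = np.random.default_rng(0)
        names = [f"V{i}" for i in range(111)] + [
            f"C{i}" for i in range(9)
        ] + ["CACO2", "MetStab", "PB", "VD", "LgBB", "SKIN"]
        X = pd.DataFrame(rng.normal(size=(10, 126)), columns=names)
        X[[f"C{i}" for i in range(9)]] = 3.14
        out, report = pretreat(X)
        assert report.kept == out.shape[1] == 111
        assert len(report.dropped_zero_variance) == 9
        assert len(report.dropped_excluded) == 6

    def test_identity_when_nothing_to_drop(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 4)))
        out, report = pretreat(X, exclude=())
        assert out.equals(X)
        assert report.kept == 4

    def test_all_constant_matrix_rejected(self):
        X = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            pretreat(X)


class TestPCA:
    def test_rank_one_matrix_explains_everything(self):
        t = np.linspace(-2, 2, 9)
        X = np.outer(t, [1.0, 2.0, -1.0])
        model = pca_fit(X, n_comp=1, scale="center_only")
        assert model.explained_pct[0] == pytest.approx(100.0)

    def test_explained_variance_non_increasing(self):
        X = np.random.default_rng(2).normal(size=(20, 6))
        model = pca_fit(X, n_comp=5)
        assert (np.diff(model.explained_pct) <= 1e-9).all()
        assert model.explained_pct.sum() <= 100 + 1e-6

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(3).normal(size=(15, 5))
        model = pca_fit(X, n_comp=3)
        gram = model.loadings.values @ model.loadings.values.T
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_planted_two_factor_variance_ratio(self):
        """Two planted factors with 4:1 variance reappear in PC1:PC2."""
        rng = np.random.default_rng(4)
        n = 400
        t1 = rng.normal(0, 2.0, n)
        t2 = rng.normal(0, 1.0, n)
        v1, _ = np.linalg.qr(rng.normal(size=(8, 2)))
        X = np.outer(t1, v1[:, 0]) + np.outer(t2, v1[:, 1])
        X += rng.normal(0, 0.01, X.shape)
        model = pca_fit(X, n_comp=2, scale="center_only")
        ratio = model.explained_pct[0] / model.explained_pct[1]
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"m{i}" for i in range(12)])
        perm = rng.permutation(12)
        a = pca_fit(X, n_comp=2).scores
        b = pca_fit(X.iloc[perm], n_comp=2).scores
        assert np.allclose(a.loc[b.index].values, b.values, atol=1e-9)

    def test_out_of_range_components(self):
        X = np.random.default_rng(6).normal(size=(4, 3))
        with pytest.raises(ValueError):
            pca_fit(X, n_comp=4)


class TestKMeans:
    def test_single_cluster_inertia_is_total_scatter(self):
        X = np.random.default_rng(7).normal(size=(10, 2))
        res = kmeans_cluster(X, k=1, seed=0)
        assert (res.labels == res.labels[0]).all()
        scatter = ((X - X.mean(axis=0)) ** 2).sum()
        assert res.inertia == pytest.approx(scatter)

    def test_separated_gaussians_recovered(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + rng.normal(0, 1.0, (20, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 20)
        res = kmeans_cluster(X, k=3, seed=1)
        # label-permutation-free comparison: co-membership must agree
        same_pred = res.labels[:, None] == res.labels[None, :]
        same_true = truth[:, None] == truth[None, :]
        assert np.array_equal(same_pred, same_true)

    def test_k_equals_n_gives_zero_inertia(self):
        X = np.random.default_rng(9).normal(size=(6, 2))
        assert kmeans_cluster(X, k=6, seed=0).inertia == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("k", [0, 7])
    def test_invalid_k(self, k):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((6, 2)), k=k)

    def test_seed_determinism(self):
        X = np.random.default_rng(10).normal(size=(30, 3))
        a = kmeans_cluster(X, k=4, seed=3)
        b = kmeans_cluster(X, k=4, seed=3)
        assert np.array_equal(a.labels, b.labels)


def ols_coefficients(X, y):
    """Normal-equations oracle: intercept + slopes by least squares."""
    A = np.column_stack([np.ones(len(X)), np.asarray(X, float)])
    beta, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
    return beta[0], beta[1:]


class TestPLS:
    def test_rank_one_exact_fit_with_one_latent_variable(self):
        t = np.linspace(0, 3, 10)
        X = np.outer(t, [1.0, -0.5, 2.0]) + 1.0
        y = X @ np.array([0.2, 0.1, -0.3])
        model = pls_fit(X, y, n_lv=1, scale="center_only")
        assert model.R2 == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_equals_ols_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 5)) * [1, 2, 0.5, 3, 1]
        y = rng.normal(size=30)
        model = pls_fit(X, y, n_lv=5)
        icpt, slopes = ols_coefficients(X, y)
        assert np.allclose(model.coefficients.values, slopes, atol=1e-8)
        assert model.intercept == pytest.approx(icpt, abs=1e-8)

    def test_matches_reference_nipals_implementation(self):
        """Cross-check against scikit-learn's PLSRegression at 3 LVs."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 8)) * 10 ** rng.uniform(-1, 1, 8)
        y = X[:, 0] * 0.5 - X[:, 3] * 2.0 + rng.normal(0, 0.5, 25)
        ours = pls_fit(X, y, n_lv=3)
        ref = PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.allclose(ours.coefficients.values, ref.coef_.ravel(), atol=1e-8)

    def test_planted_coefficient_recovery(self):
        X, y, beta = gen_pls_dataset(PlantedPLSConfig(seed=13))
        model = pls_fit(X, y, n_lv=10)
        r = np.corrcoef(model.coefficients.values, beta)[0, 1]
        assert r > 0.95

    def test_orthogonal_design_equals_per_column_regression(self):
        """On orthogonal centred X, full-LV PLS slopes equal x_j.y/x_j.x_j."""
        rng = np.random.default_rng(14)
        g = rng.normal(size=(20, 4))
        g -= g.mean(axis=0)  # zero-mean first, so QR columns stay centred
        q, _ = np.linalg.qr(g)
        y = rng.normal(size=20)
        model = pls_fit(q, y, n_lv=4, scale="center_only")
        yc = y - y.mean()
        per_column = np.array([q[:, j] @ yc / (q[:, j] @ q[:, j]) for j in range(4)])
        assert np.allclose(model.coefficients.values, per_column, atol=1e-8)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(15).normal(size=(8, 3))
        with pytest.raises(ValueError):
            pls_fit(X, np.ones(8), n_lv=2)

    def test_n_lv_beyond_rank_rejected(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, 3.0])  # rank 1
        with pytest.raises(ValueError):
            pls_fit(X, t, n_lv=2)


class TestLooQ2:
    def test_noiseless_linear_response_predicts_well(self):
        X, y, _ = gen_pls_dataset(
            PlantedPLSConfig(n_samples=80, n_descriptors=10, n_informative=3,
                             noise_sd=0.0, seed=16)
        )
        q2, press = loo_q2(X, y, n_lv=3)
        assert q2 > 0.99
        assert press >= 0

    def test_q2_not_above_r2(self):
        for seed in range(5):
            X, y, _ = gen_pls_dataset(
                PlantedPLSConfig(n_samples=30, n_descriptors=8, n_informative=3,
                                 noise_sd=0.3, seed=seed)
            )
            model = pls_fit(X, y, n_lv=4)
            q2, _ = loo_q2(X, y, n_lv=4)
            assert q2 <= model.R2

    def test_permuted_response_has_no_predictivity(self):
        """Median LOO Q2 over permutations of y against X is not positive."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        q2s = []
        for _ in range(30):
            q2, _ = loo_q2(X, rng.permutation(y), n_lv=3)
            q2s.append(q2)
        assert np.median(q2s) <= 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            loo_q2(np.eye(2), np.array([0.0, 1.0]), n_lv=1)


class TestSelectFeatures:
    def test_explicit_list_identity(self, paper):
        X = pd.DataFrame(
            np.random.default_rng(18).normal(size=(5, 18)),
            columns=paper.selected18,
        )
        assert select_features(X, names=paper.selected18) == paper.selected18

    def test_unknown_name_rejected(self):
        X = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        with pytest.raises(KeyError):
            select_features(X, names=["a", "zz"])

    def test_forward_q2_finds_planted_pair(self):
        """y built from 2 of 20 columns: greedy forward selection returns
        exactly that pair in at least 90% of seeded runs."""
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(
                rng.normal(size=(30, 20)), columns=[f"c{i}" for i in range(20)]
            )
            y = 2.0 * X["c3"].values - 1.5 * X["c11"].values + rng.normal(0, 0.1, 30)
            chosen = select_features(X, y, mode="forward_q2", n_lv=2, tol=0.01)
            hits += set(chosen) == {"c3", "c11"}
        assert hits >= 0.9 * runs
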