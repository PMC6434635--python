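"""t-test feature selection and locally linear embedding."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import special_ortho_group

import dticlass as dc
from dticlass.features import (lle_fit, lle_transform, select_top_features,
                               ttest_scores)


class TestTTestScores:
    def test_identical_groups_t_zero_p_one(self):
        X = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (2, 1))
        y = np.array([1, 1, 0, 0])
        t, p, _ = ttest_scores(X, y)
        assert (t == 0).all()
        assert (p == 1).all()

    def test_zero_variance_identical_means_flagged(self):
        X = np.full((6, 3), 2.5)
        y = np.array([1, 1, 1, 0, 0, 0])
        t, p, degenerate = ttest_scores(X, y)
        assert (t == 0).all()
        assert (p == 1).all()
        assert degenerate.all()

    def test_hand_computed_example(self):
        # patients {1,2,3}, controls {4,5,6}: pooled sd = 1,
        # se = sqrt(2/3), t = -3/se = -3.674
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        t, p, _ = ttest_scores(X, y)
        assert t[0] == pytest.approx(-3.674, abs=5e-4)

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy_reference(self, equal_var):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 40))
        y = (rng.uniform(size=25) < 0.4).astype(int)
        y[:2] = 1
        y[-2:] = 0
        t, p, _ = ttest_scores(X, y, equal_var=equal_var)
        ref_t, ref_p = stats.ttest_ind(X[y == 1], X[y == 0],
                                       equal_var=equal_var)
        assert np.allclose(t, ref_t, atol=1e-10)
        assert np.allclose(p, ref_p, atol=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ttest_scores(np.ones((3, 2)), np.array([1, 0, 0]))


class TestSelectTopFeatures:
    def test_select_all(self):
        t = np.array([1.0, -2.0, 0.5])
        p = np.array([0.3, 0.05, 0.6])
        res = select_top_features(t, p, 3)
        assert set(res.selected.tolist()) == {0, 1, 2}
        assert res.selected[0] == 1  # smallest p first

    def test_single_informative_feature_found(self):
        hits = 0
        rng_master = np.random.default_rng(0)
        for _ in range(100):
            seed = int(rng_master.integers(2**31))
            tab = dc.gen_feature_cohort(dc.CohortSpec(
                n_patients=15, n_controls=15, n_features=50,
                informative=(7,), effect=3.0, seed=seed))
            t, p, deg = ttest_scores(tab.X, tab.y)
            res = select_top_features(t, p, 1, degenerate=deg)
            hits += res.selected[0] == 7
        assert hits / 100 > 0.99

    def test_exact_ties_deterministic(self):
        # duplicated feature columns produce exactly tied (t, p):
        # the tie rule keeps the lower feature index
        rng = np.random.default_rng(1)
        col = rng.normal(size=10)
        X = np.column_stack([col, col])
        y = np.array([1] * 5 + [0] * 5)
        t, p, _ = ttest_scores(X, y)
        assert t[0] == t[1] and p[0] == p[1]
        res = select_top_features(t, p, 1)
        assert res.selected[0] == 0  # tie broken by lower feature index

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            select_top_features(np.ones(3), np.ones(3), 0)
        with pytest.raises(ValueError):
            select_top_features(np.ones(3), np.ones(3), 4)

    def test_label_permutation_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 15))
        y = np.array([1] * 8 + [0] * 12)
        t1, p1, _ = ttest_scores(X, y)
        perm = rng.permutation(20)
        t2, p2, _ = ttest_scores(X[perm], y[perm])
        assert np.allclose(t1, t2, atol=1e-12)
        sel1 = select_top_features(t1, p1, 5).selected
        sel2 = select_top_features(t2, p2, 5).selected
        assert (sel1 == sel2).all()


class TestLLEFit:
    def test_line_manifold_preserves_ordering(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 1, 30))
        X = np.outer(t, rng.normal(size=10))
        emb = lle_fit(X, k=5, d=1).embedding[:, 0]
        diffs = np.diff(emb)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        model = lle_fit(X, k=6, d=3)
        assert np.abs(model.W.sum(axis=1) - 1.0).max() < 1e-10
        # weights only on the k nearest neighbors
        assert (np.count_nonzero(model.W, axis=1) <= 6).all()

    def test_embedding_zero_mean_unit_norm(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(35, 9))
        emb = lle_fit(X, k=7, d=4).embedding
        assert np.abs(emb.mean(axis=0)).max() < 1e-8
        assert np.allclose(np.linalg.norm(emb, axis=0), 1.0, atol=1e-8)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 6))
        R = special_ortho_group.rvs(6, random_state=rng)
        X2 = X @ R.T + rng.normal(size=6)
        e1 = lle_fit(X, k=6, d=2).embedding
        e2 = lle_fit(X2, k=6, d=2).embedding
        for j in range(2):
            corr = np.corrcoef(e1[:, j], e2[:, j])[0, 1]
            assert abs(corr) > 1 - 1e-6

    def test_matches_dense_eigendecomposition_oracle(self):
        # brute-force oracle: rebuild M = (I-W)^T(I-W) from the model's
        # weights and solve with an independent eigensolver
        from scipy.linalg import eigh as scipy_eigh

        rng = np.random.default_rng(8)
        X = rng.normal(size=(45, 7))
        model = lle_fit(X, k=8, d=3)
        M = (np.eye(45) - model.W).T @ (np.eye(45) - model.W)
        vals, vecs = scipy_eigh(M)
        for j in range(3):
            ref = vecs[:, j + 1]
            got = model.embedding[:, j]
            assert min(np.abs(got - ref).max(),
                       np.abs(got + ref).max()) < 1e-8
        assert np.allclose(model.eigenvalues, vals[1:4], atol=1e-10)

    def test_matches_sklearn_reference(self):
        # structured 2-D manifold (a degenerate spectrum on pure-noise
        # clouds would make the comparison ill-posed); sklearn's
        # regularizer is reg*trace(G) vs our reg*trace(G)/k, so reg=k*1e-3
        # makes the two solves identical
        from sklearn.manifold import LocallyLinearEmbedding

        rng = np.random.default_rng(9)
        t = rng.uniform(0, 1, (40, 2))
        X = t @ rng.normal(size=(2, 6)) + 0.01 * rng.normal(size=(40, 6))
        ours = lle_fit(X, k=6, d=2, reg=6e-3).embedding
        ref = LocallyLinearEmbedding(
            n_neighbors=6, n_components=2, reg=1e-3,
            eigen_solver="dense").fit_transform(X)
        for j in range(2):
            corr = np.corrcoef(ours[:, j], ref[:, j])[0, 1]
            assert abs(corr) > 1 - 1e-6

    def test_parameter_validation(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="k="):
            lle_fit(X, k=5, d=2)
        with pytest.raises(ValueError, match="points"):
            lle_fit(np.zeros((3, 3)), k=2, d=3)

    def test_duplicate_points_warn_but_fit(self):
        X = np.zeros((10, 4))
        X[5:] = 1.0
        with pytest.warns(UserWarning, match="duplicate|singular"):
            model = lle_fit(X, k=3, d=1)
        assert np.isfinite(model.embedding).all()


class TestLLETransform:
    def test_training_point_maps_to_own_embedding(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 5))
        model = lle_fit(X, k=5, d=2)
        out = lle_transform(model, X[11])
        assert np.abs(out - model.embedding[11]).max() < 1e-8

    def test_midpoint_stays_between_neighbors(self):
        # points on a line: the midpoint of two adjacent training points
        # must embed within the segment between their embeddings
        t = np.linspace(0, 1, 20)
        X = np.outer(t, np.ones(6))
        model = lle_fit(X, k=4, d=1)
        mid = (X[8] + X[9]) / 2
        out = lle_transform(model, mid)[0]
        lo, hi = sorted([model.embedding[8, 0], model.embedding[9, 0]])
        assert lo - 1e-9 <= out <= hi + 1e-9

    def test_training_order_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 5))
        x_new = rng.normal(size=5)
        m1 = lle_fit(X, k=5, d=2)
        perm = rng.permutation(30)
        m2 = lle_fit(X[perm], k=5, d=2)
        o1 = lle_transform(m1, x_new)
        o2 = lle_transform(m2, x_new)
        # embeddings agree up to per-component sign
        for j in range(2):
            assert min(abs(o1[j] - o2[j]), abs(o1[j] + o2[j])) < 1e-8

    def test_dimension_mismatch_rejected(self):
        model = lle_fit(np.zeros((10, 4)) + np.arange(10)[:, None],
                        k=3, d=1)
        with pytest.raises(ValueError, match="dimension"):
            lle_transform(model, np.zeros(5))

    def test_batch_transform_matches_single(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 4))
        model = lle_fit(X, k=4, d=2)
        news = rng.normal(size=(3, 4))
        batch = lle_transform(model, news)
        singles = np.vstack([lle_transform(model, n) for n in news])
        assert np.allclose(batch, singles, atol=1e-12)
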