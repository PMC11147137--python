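"""OPLS / OPLS-DA correctness, VIP identities, PCA, double CV, and
permutation testing.

The independent oracle for OPLS predictions is scikit-learn's NIPALS
PLSRegression: an OPLS model with one predictive and k orthogonal
components must predict y identically to a (k+1)-component PLS fit.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.cross_decomposition import PLSRegression

from vitdmet.crossval import double_cv, permutation_test
from vitdmet.opls import OPLS, OPLSDA, fit_pca, select_vip, vip_scores


def _random_instance(rng, n=40, p=15):
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return X, y


class TestPca:
    def test_two_variable_explained_fraction(self, rng):
        a = rng.standard_normal(200)
        b = 0.8 * a + 0.6 * rng.standard_normal(200)
        X = np.column_stack([a, b])
        X = (X - X.mean(0)) / X.std(0, ddof=0)
        rho = np.corrcoef(X.T)[0, 1]
        model = fit_pca(X, 2)
        # eigenvalues of a 2x2 correlation matrix are 1 +/- rho
        np.testing.assert_allclose(model.explained_variance_fraction[0],
                                   (1 + abs(rho)) / 2, atol=1e-10)

    def test_rank_one_data(self, rng):
        t = rng.standard_normal(30)
        X = np.outer(t, [1.0, 2.0, -1.0])
        model = fit_pca(X, 2)
        np.testing.assert_allclose(model.explained_variance_fraction, [1.0, 0.0],
                                   atol=1e-10)

    def test_rotation_invariance_of_explained_fractions(self, rng):
        X = rng.standard_normal((50, 8))
        R, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        f1 = fit_pca(X, 4).explained_variance_fraction
        f2 = fit_pca(X @ R, 4).explained_variance_fraction
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_loadings_orthonormal_scores_consistent(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 6)))
        m = fit_pca(X, 3)
        L = m.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(
            m.scores.to_numpy(), (X.to_numpy() - m.mean_) @ L, atol=1e-8)
        # deterministic orientation: dominant loading entry positive
        for j in range(3):
            col = L[:, j]
            assert col[np.argmax(np.abs(col))] > 0
        assert np.all(np.diff(m.explained_variance_fraction) <= 1e-12)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((5, 10)), 5)


class TestOpls:
    def test_zero_ortho_equals_one_component_pls(self, rng):
        X, y = _random_instance(rng)
        model = OPLS(n_ortho=0).fit(X, y)
        pls = PLSRegression(n_components=1, scale=False).fit(X, y)
        Xnew = rng.standard_normal((10, X.shape[1]))
        np.testing.assert_allclose(model.predict(Xnew),
                                   pls.predict(Xnew).ravel(), atol=1e-8)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_prediction_equivalence_with_pls_oracle(self, rng, k):
        """OPLS(1 predictive + k orthogonal) predicts y exactly like a
        (k+1)-component NIPALS PLS regression."""
        for _ in range(5):
            X, y = _random_instance(rng)
            model = OPLS(n_ortho=k).fit(X, y)
            pls = PLSRegression(n_components=k + 1, scale=False).fit(X, y)
            Xnew = rng.standard_normal((12, X.shape[1]))
            np.testing.assert_allclose(model.predict(Xnew),
                                       pls.predict(Xnew).ravel(), atol=1e-6)

    def test_planted_structure_recovered_exactly(self, rng):
        """X built noiselessly from one y-proportional and one y-orthogonal
        factor is explained fully (R2Y = 1) with a single orthogonal
        component."""
        n, p = 40, 10
        y = rng.standard_normal(n)
        yc = y - y.mean()
        to = rng.standard_normal(n)
        to -= to.mean()
        to -= (to @ yc) / (yc @ yc) * yc
        pv = rng.standard_normal(p)
        pov = rng.standard_normal(p)
        X = np.outer(yc, pv) + np.outer(to, pov)
        model = OPLS(n_ortho=1).fit(X, y)
        assert model.r2y_ > 1 - 1e-6

    def test_variance_conservation_and_orthogonality(self, rng):
        X, y = _random_instance(rng, n=50, p=20)
        model = OPLS(n_ortho=3).fit(X, y)
        Xc = X - X.mean(0)
        recon = (np.outer(model.predictive_scores_, model.predictive_loadings_)
                 + model.orthogonal_scores_ @ model.orthogonal_loadings_)
        E = Xc - recon
        np.testing.assert_allclose((E ** 2).sum(),
                                   (1 - model.r2x_) * (Xc ** 2).sum(), rtol=1e-6)
        yc = y - y.mean()
        for j in range(model.n_ortho_):
            r = np.corrcoef(model.orthogonal_scores_[:, j], yc)[0, 1]
            assert abs(r) < 1e-6
            assert abs(model.predictive_weights_ @ model.orthogonal_weights_[j]) < 1e-8
        # predictive scores uncorrelated with each orthogonal score
        for j in range(model.n_ortho_):
            r = np.corrcoef(model.predictive_scores_,
                            model.orthogonal_scores_[:, j])[0, 1]
            assert abs(r) < 1e-8

    def test_sign_convention_dominant_loading_positive(self, rng):
        X, y = _random_instance(rng)
        model = OPLS(n_ortho=2).fit(X, y)
        pl = model.predictive_loadings_
        assert pl[np.argmax(np.abs(pl))] > 0
        for po in model.orthogonal_loadings_:
            assert po[np.argmax(np.abs(po))] > 0

    def test_constant_y_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="constant"):
            OPLS(n_ortho=0).fit(X, np.ones(20))

    def test_excessive_n_ortho_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            OPLS(n_ortho=6).fit(X, rng.standard_normal(10))


class TestOplsda:
    def test_label_swap_symmetry(self, rng):
        X = rng.standard_normal((40, 12))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        m1 = OPLSDA(n_ortho=1).fit(X, labels)
        m2 = OPLSDA(n_ortho=1).fit(X, labels[::-1][np.argsort(np.arange(40))])
        # swapping the class coding negates the decision values
        swapped = np.where(labels == "a", "b", "a")
        m3 = OPLSDA(n_ortho=1).fit(X, swapped)
        np.testing.assert_allclose(m3.decision_function(X),
                                   -m1.decision_function(X), atol=1e-8)
        # VIP is direction-free
        np.testing.assert_allclose(vip_scores(m3).to_numpy(),
                                   vip_scores(m1).to_numpy(), atol=1e-8)
        # scores agree up to one global sign
        s1, s3 = m1.predictive_scores_, m3.predictive_scores_
        assert (np.allclose(s1, s3, atol=1e-8) or np.allclose(s1, -s3, atol=1e-8))

    def test_perfectly_separated_classes(self, rng):
        n = 30
        axis = np.r_[rng.uniform(1, 2, n), rng.uniform(-2, -1, n)]
        direction = rng.standard_normal(8)
        X = np.outer(axis, direction) + 0.01 * rng.standard_normal((2 * n, 8))
        labels = np.array([1] * n + [0] * n)
        model = OPLSDA(n_ortho=0).fit(X, labels)
        s = model.predictive_scores_
        assert max(s[labels == 0].max(), -s[labels == 1].min()) < \
            min(s[labels == 1].max(), -s[labels == 0].min()) or \
            (s[labels == 1].min() > s[labels == 0].max()
             or s[labels == 0].min() > s[labels == 1].max())
        assert (model.predict(X) == labels).all()

    def test_class_requirements(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="two classes"):
            OPLSDA().fit(X, np.zeros(10))
        with pytest.raises(ValueError, match="at least 2"):
            OPLSDA().fit(X, np.r_[np.zeros(9), 1.0])


class TestVip:
    def test_unit_weight_example(self, rng):
        """With orthonormal centred columns and y = X @ (0.6, 0.8) the
        predictive weight is exactly (0.6, 0.8) and VIP = sqrt(2)|w|."""
        A = rng.standard_normal((20, 2))
        Q, _ = np.linalg.qr(A - A.mean(0))
        y = Q @ np.array([0.6, 0.8])
        model = OPLS(n_ortho=0).fit(Q, y)
        vip = vip_scores(model).to_numpy()
        np.testing.assert_allclose(np.sort(vip), [0.6 * np.sqrt(2), 0.8 * np.sqrt(2)],
                                   atol=1e-8)
        np.testing.assert_allclose(vip, [0.8485, 1.1314], atol=1e-3)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(5, 40))
    def test_mean_squared_vip_is_one(self, seed, p):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((max(p // 2, 8) + 5, p))
        y = rng.standard_normal(X.shape[0])
        vip = vip_scores(OPLS(n_ortho=0).fit(X, y))
        assert abs((vip ** 2).mean() - 1.0) < 1e-8

    def test_null_fit_vip_below_bound(self, rng):
        X = rng.standard_normal((60, 300))
        y = rng.standard_normal(60)
        vip = vip_scores(OPLS(n_ortho=1).fit(X, y))
        assert vip.max() < np.sqrt(300)
        assert (vip >= 0).all()

    def test_select_vip_strict_threshold_and_order(self):
        vip = pd.Series({"a": 2.5, "b": 1.9, "c": 2.0})
        assert select_vip(vip, 2.0) == ["a"]
        assert select_vip(vip, 1.0) == ["a", "c", "b"]
        with pytest.raises(ValueError):
            select_vip(vip, 0.0)

    def test_empty_selection_allowed(self):
        assert select_vip(pd.Series({"a": 0.5}), 2.0) == []


class TestDoubleCv:
    def test_noiseless_linear_target(self, rng):
        T = rng.standard_normal((60, 3))
        P = rng.standard_normal((3, 12))
        X = T @ P
        y = X @ rng.standard_normal(12)
        assert double_cv(X, y, seed=2).q2 > 0.99

    def test_null_q2_not_optimistic(self, rng):
        q2 = [double_cv(rng.standard_normal((100, 50)),
                        rng.standard_normal(100), seed=s).q2 for s in range(5)]
        assert np.mean(q2) <= 0.05

    def test_deterministic_given_seed(self, rng):
        X, y = rng.standard_normal((45, 10)), rng.standard_normal(45)
        assert double_cv(X, y, seed=7).q2 == double_cv(X, y, seed=7).q2

    def test_fold_size_errors(self, rng):
        X, y = rng.standard_normal((12, 4)), rng.standard_normal(12)
        with pytest.raises(ValueError, match="folds"):
            double_cv(X, y, outer_folds=13)
        with pytest.raises(ValueError, match="< 2 samples"):
            double_cv(X, y, outer_folds=10)


class TestPermutationTest:
    def test_p_value_matches_formula_and_bounds(self, rng):
        X, y = rng.standard_normal((40, 8)), rng.standard_normal(40)
        res = permutation_test(X, y, n_perm=49, seed=3, inner_folds=4, max_ortho=2)
        expected = (1 + np.sum(res.permuted_q2 >= res.observed_q2)) / 50
        assert res.p_value == expected
        assert 1 / 50 <= res.p_value <= 1.0

    def test_strong_signal_reaches_floor(self, rng):
        X = rng.standard_normal((120, 30))
        y = X @ rng.standard_normal(30) + 0.05 * rng.standard_normal(120)
        res = permutation_test(X, y, n_perm=99, seed=5, max_ortho=2)
        assert res.p_value == 1 / 100

    def test_deterministic(self, rng):
        X, y = rng.standard_normal((40, 8)), rng.standard_normal(40)
        a = permutation_test(X, y, n_perm=20, seed=9, inner_folds=4, max_ortho=2)
        b = permutation_test(X, y, n_perm=20, seed=9, inner_folds=4, max_ortho=2)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.permuted_q2, b.permuted_q2)


class TestScaleEquivariance:
    def test_y_scaling_leaves_vip_q2_p_unchanged(self, rng):
        X, y = rng.standard_normal((50, 15)), rng.standard_normal(50)
        v1 = vip_scores(OPLS(n_ortho=1).fit(X, y)).to_numpy()
        v2 = vip_scores(OPLS(n_ortho=1).fit(X, 3.7 * y)).to_numpy()
        np.testing.assert_allclose(v1, v2, atol=1e-8)
        assert abs(double_cv(X, y, seed=1).q2
                   - double_cv(X, 3.7 * y, seed=1).q2) < 1e-8
        p1 = permutation_test(X, y, n_perm=30, seed=2, inner_folds=4, max_ortho=2)
        p2 = permutation_test(X, 3.7 * y, n_perm=30, seed=2, inner_folds=4, max_ortho=2)
        assert abs(p1.p_value - p2.p_value) < 1e-12
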