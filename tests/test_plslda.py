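"""NIPALS PLS, PRESS component selection, LDA, and the composed classifier."""

import numpy as np
import pytest

from cortexfuse.plslda import (
    LdaModel,
    PlsLdaModel,
    fit_lda,
    fit_pls,
    fit_plslda,
    predict,
    select_components_press,
)


def two_gaussians(rng, n_per_class, d, separation, cov=None):
    """Equal-covariance Gaussian classes separated along the first axis."""
    mu = np.zeros(d)
    mu[0] = separation
    X0 = rng.standard_normal((n_per_class, d))
    X1 = rng.standard_normal((n_per_class, d)) + mu
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    return X, y


class TestFitPls:
    def test_single_feature_equals_simple_regression(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = (x > 0).astype(float)
        model = fit_pls(x[:, None], y, A=1)
        # closed-form simple least squares of y on x
        b = np.cov(x, y, bias=True)[0, 1] / x.var()
        a = y.mean() - b * x.mean()
        pred = model.predict_y(x[:, None])
        assert np.allclose(pred, a + b * x, atol=1e-9)

    def test_rank_one_x_exhausts_after_first_component(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=30)
        X = np.outer(u, [1.0, -2.0, 0.5])  # rank 1
        y = (u > 0).astype(float)
        with pytest.warns(UserWarning, match="exhausted"):
            model = fit_pls(X, y, A=3)
        assert model.A == 1

    def test_duplicated_feature_leaves_y_scores_unchanged(self):
        rng = np.random.default_rng(2)
        X, y = two_gaussians(rng, 15, 4, 2.0)
        # at full rank both fits reproduce the least-squares prediction on
        # the (identical) column span, so the y-scores coincide exactly
        m1 = fit_pls(X, y, A=4)
        m2 = fit_pls(np.hstack([X, X[:, [0]]]), y, A=4)
        assert np.allclose(m1.predict_y(X),
                           m2.predict_y(np.hstack([X, X[:, [0]]])), atol=1e-8)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(3)
        X, y = two_gaussians(rng, 20, 6, 1.0)
        model = fit_pls(X, y, A=4)
        G = model.T.T @ model.T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(model.A)
        assert np.abs(off).max() < 1e-8

    def test_full_rank_pls_matches_ordinary_least_squares(self):
        rng = np.random.default_rng(4)
        X, y = two_gaussians(rng, 20, 5, 1.5)
        model = fit_pls(X, y, A=5)
        Xc = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        assert np.allclose(model.predict_y(X), Xc @ beta, atol=1e-6)

    def test_matches_reference_pls_regression(self):
        """Cross-check against scikit-learn's PLSRegression predictions."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X, y = two_gaussians(rng, 25, 6, 1.0)
        for A in (1, 2, 4):
            ours = fit_pls(X, y, A=A).predict_y(X)
            ref = sklearn.PLSRegression(n_components=A, scale=False)
            ref.fit(X, y)
            assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_pls(np.random.default_rng(6).normal(size=(5, 2)),
                    np.zeros(5), A=1)


class TestSelectComponentsPress:
    def test_noiseless_rank_one_relation_selects_one(self):
        rng = np.random.default_rng(7)
        w = np.array([1.0, -0.5, 2.0])
        Z = rng.normal(size=(30, 3))
        y = np.r_[np.zeros(15), np.ones(15)]
        X = np.outer(y - y.mean(), w) + 0.0 * Z  # exact rank-1 link
        assert select_components_press(X, y, A_max=3) == 1

    def test_pure_noise_prefers_one_component(self):
        """PRESS penalizes overfit components under the null."""
        picks = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 5))
            y = np.r_[np.zeros(30), np.ones(30)]
            picks.append(select_components_press(X, y, A_max=4))
        picks = np.array(picks)
        freq = [(picks == k).mean() for k in (1, 2, 3, 4)]
        assert freq[0] >= 0.7  # K=1 dominates under the null
        assert all(freq[i] > freq[i + 1] for i in range(3))

    def test_amax_one_is_trivial(self):
        rng = np.random.default_rng(8)
        X, y = two_gaussians(rng, 10, 3, 1.0)
        assert select_components_press(X, y, A_max=1) == 1


class TestFitLda:
    def test_hand_arithmetic_one_dimensional(self):
        T = np.array([[-1.1], [-0.9], [0.9], [1.1]])
        y = np.array([0, 0, 1, 1])
        model = fit_lda(T, y)
        assert np.allclose(model.means.ravel(), [-1.0, 1.0])
        assert model.cov[0, 0] == pytest.approx(0.02)

    def test_identical_classes_tie_breaks_to_class_zero(self):
        rng = np.random.default_rng(9)
        T = np.tile(rng.normal(size=(4, 2)), (2, 1))
        y = np.r_[np.zeros(4), np.ones(4)]
        model = fit_lda(T, y)
        assert np.allclose(model.means[0], model.means[1])
        pls_stub = _identity_pls(2)
        composed = PlsLdaModel(pls=pls_stub, lda=model, n_components=2)
        cls, score = predict(composed, np.array([0.3, -0.2]))
        assert score == pytest.approx(0.0, abs=1e-12)
        assert cls == 0

    def test_pooled_covariance_matches_naive_loop(self):
        rng = np.random.default_rng(10)
        T = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, size=40)
        y[:2], y[-2:] = 0, 1
        model = fit_lda(T, y)
        scatter = np.zeros((2, 2))
        for g in (0, 1):
            Tg = T[y == g]
            mu = Tg.mean(axis=0)
            for row in Tg:
                scatter += np.outer(row - mu, row - mu)
        assert np.allclose(model.cov, scatter / (40 - 2), atol=1e-12)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_lda(np.zeros((3, 1)), np.array([0, 1, 1]))


def _identity_pls(d):
    """A PLS stub whose latent scores are the raw inputs (W=P=I)."""
    from cortexfuse.plslda import PlsModel

    return PlsModel(
        x_mean=np.zeros(d), y_mean=0.5, x_scale=np.ones(d),
        W=np.eye(d), P=np.eye(d), q=np.ones(d), beta=np.zeros(d),
        T=np.zeros((2, d)), A=d,
    )


class TestPredict:
    def make_1d_model(self, mu0=-1.0, mu1=1.0, var=1.0):
        lda = LdaModel(means=np.array([[mu0], [mu1]]),
                       cov=np.array([[var]]), priors=np.array([0.5, 0.5]))
        return PlsLdaModel(pls=_identity_pls(1), lda=lda, n_components=1)

    def test_nearer_mean_wins(self):
        model = self.make_1d_model()
        cls, score = predict(model, np.array([0.2]))
        assert cls == 1 and score > 0

    def test_exact_class_mean_assigns_that_class(self):
        model = self.make_1d_model(mu0=-3.0, mu1=0.5, var=17.0)
        cls, _ = predict(model, np.array([-3.0]))
        assert cls == 0
        cls, _ = predict(model, np.array([0.5]))
        assert cls == 1

    def test_well_separated_gaussians_reach_bayes_accuracy(self):
        """6 sigma between means: accuracy should match Phi(3) ~ 0.9987."""
        rng = np.random.default_rng(11)
        X_tr, y_tr = two_gaussians(rng, 100, 2, 6.0)
        model = fit_plslda(X_tr, y_tr, A_max=2)
        X_te, y_te = two_gaussians(rng, 500, 2, 6.0)
        cls, _ = predict(model, X_te)
        assert (cls == y_te).mean() >= 0.99

    def test_decision_invariant_under_linear_map_of_latent_space(self):
        rng = np.random.default_rng(12)
        T = rng.normal(size=(30, 2))
        y = np.r_[np.zeros(15), np.ones(15)]
        T[y == 1] += [2.0, -1.0]
        lda = fit_lda(T, y)
        M = np.array([[1.5, 0.3], [-0.2, 0.8]])  # invertible
        lda_mapped = fit_lda(T @ M.T, y)
        pts = rng.normal(size=(50, 2))
        from cortexfuse.plslda import _discriminant_scores

        s1 = _discriminant_scores(lda, pts)
        s2 = _discriminant_scores(lda_mapped, pts @ M.T)
        assert np.allclose(s1, s2, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        model = self.make_1d_model()
        with pytest.raises(ValueError, match="features"):
            predict(model, np.array([1.0, 2.0]))


class TestFitPlsLda:
    def test_linearly_separable_training_accuracy_one(self):
        rng = np.random.default_rng(13)
        X, y = two_gaussians(rng, 10, 3, 20.0)
        model = fit_plslda(X, y, A_max=3)
        cls, _ = predict(model, X)
        assert (cls == y).mean() == 1.0

    def test_label_permuted_training_accuracy_bounded(self):
        """With d=5 and K<=2, overfitting cannot memorize random labels."""
        accs = []
        for seed in range(100):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 5))
            y = rng.permutation(np.r_[np.zeros(30), np.ones(30)])
            model = fit_plslda(X, y, A_max=2)
            cls, _ = predict(model, X)
            accs.append((cls == y).mean())
        accs = np.array(accs)
        assert 0.5 < accs.mean() < 0.75
        assert accs.max() < 1.0

    def test_refit_is_bit_reproducible(self):
        rng = np.random.default_rng(14)
        X, y = two_gaussians(rng, 20, 4, 1.0)
        m1 = fit_plslda(X, y, A_max=4)
        m2 = fit_plslda(X, y, A_max=4)
        assert m1.n_components == m2.n_components
        assert np.array_equal(m1.pls.W, m2.pls.W)
        assert np.array_equal(m1.lda.cov, m2.lda.cov)

    def test_prediction_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(15)
        X, y = two_gaussians(rng, 25, 4, 2.0)
        m1 = fit_plslda(X, y, A_max=3)
        X2 = X.copy()
        X2[:, 2] = X2[:, 2] * 1000.0 + 5.0
        m2 = fit_plslda(X2, y, A_max=3, autoscale=True)
        m1s = fit_plslda(X, y, A_max=3, autoscale=True)
        Xt, yt = two_gaussians(rng, 40, 4, 2.0)
        Xt2 = Xt.copy()
        Xt2[:, 2] = Xt2[:, 2] * 1000.0 + 5.0
        c1, _ = predict(m1s, Xt)
        c2, _ = predict(m2, Xt2)
        assert (c1 == c2).all()

    def test_json_round_trip_reproduces_predictions(self):
        rng = np.random.default_rng(16)
        X, y = two_gaussians(rng, 15, 3, 1.5)
        model = fit_plslda(X, y, A_max=3)
        back = PlsLdaModel.from_json(model.to_json())
        Xt, _ = two_gaussians(rng, 10, 3, 1.5)
        c1, s1 = predict(model, Xt)
        c2, s2 = predict(back, Xt)
        assert (c1 == c2).all()
        assert np.allclose(s1, s2, atol=1e-12)
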