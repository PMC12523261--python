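import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from specgrain._pls import loo_rmse_by_components, pls1_coefficients
from specgrain.errors import FitError, ShapeError
from specgrain.models import fit_bpnn, fit_cnn, fit_plsr, fit_svr, predict


class TestPLSCore:
    def test_nipals_matches_sklearn(self, rng):
        """The internal nested-components PLS1 agrees with sklearn's
        PLSRegression at every component count (independent route)."""
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.1, 30)
        B, c = pls1_coefficients(X, y, 6)
        for a in (1, 2, 4, 6):
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(X @ B[a - 1] + c[a - 1],
                               ref.predict(X).ravel(), atol=1e-8)

    def test_loo_rmse_matches_manual_loop(self, rng):
        X = rng.normal(size=(15, 6))
        y = X @ np.arange(1.0, 7.0) + rng.normal(0, 0.2, 15)
        loo = loo_rmse_by_components(X, y, 3)
        for a in (1, 3):
            errs = []
            for i in range(15):
                mask = np.ones(15, dtype=bool)
                mask[i] = False
                ref = PLSRegression(n_components=a, scale=False)
                ref.fit(X[mask], y[mask])
                errs.append(ref.predict(X[i:i + 1]).item() - y[i])
            assert loo[a - 1] == pytest.approx(
                np.sqrt(np.mean(np.square(errs))), abs=1e-8)


class TestPLSR:
    def test_full_components_equal_ols(self, rng):
        """With as many latent factors as full-rank columns, PLSR reproduces
        the normal-equations solution."""
        X = rng.normal(size=(24, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0, -1.0]) + rng.normal(0, 0.3, 24)
        model = fit_plsr(X, y, component_grid=[5], folds=4)
        A = np.column_stack([np.ones(24), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(model.predict(X), A @ beta, atol=1e-8)

    def test_rank_one_proportional_case(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        model = fit_plsr(X, y, component_grid=[1], folds=2)
        assert np.allclose(model.predict(X), y, atol=1e-10)

    def test_exact_linear_target_recovered(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ np.arange(1.0, 7.0)
        model = fit_plsr(X, y, component_grid=range(1, 7), folds=5)
        assert np.allclose(model.predict(X), y, atol=1e-6)

    def test_constant_target_raises(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(FitError):
            fit_plsr(X, np.ones(20), component_grid=[1], folds=4)


class TestSVR:
    def test_linear_limit(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5])
        model = fit_svr(X, y, kernels=("linear",), C_grid=[1e3],
                        gamma_modes=("scale",), folds=5)
        r = np.corrcoef(model.predict(X), y)[0, 1]
        assert r >= 0.999

    def test_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(20, 4))
        model = fit_svr(X, np.full(20, 5.0), kernels=("rbf",), C_grid=[1.0],
                        gamma_modes=("scale",), folds=4)
        assert np.allclose(model.predict(X), 5.0, atol=0.11)  # epsilon tube

    def test_grid_winner_matches_exhaustive_loop(self, rng):
        """The tuned (kernel, C, gamma) cell equals the argmin of a
        brute-force CV loop over all grid cells."""
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR as SkSVR

        X = rng.normal(size=(30, 5))
        y = X @ np.array([1.0, 0.5, -1.0, 2.0, 0.0]) + rng.normal(0, 0.2, 30)
        kernels, Cs, gammas = ("linear", "rbf"), [0.1, 1.0, 10.0], ("scale", "auto")
        model = fit_svr(X, y, kernels=kernels, C_grid=Cs, gamma_modes=gammas,
                        folds=5)

        # same scoring convention as the tuner: mean of per-fold RMSEs
        def cell_score(k, C, g):
            scores = []
            for tr, te in KFold(n_splits=5).split(X):
                pipe = Pipeline([("scale", StandardScaler()),
                                 ("svr", SkSVR(kernel=k, C=C, gamma=g))])
                pipe.fit(X[tr], y[tr])
                scores.append(np.sqrt(np.mean((pipe.predict(X[te]) - y[te]) ** 2)))
            return np.mean(scores)

        cells = {(k, C, g): cell_score(k, C, g)
                 for k in kernels for C in Cs for g in gammas}
        winner = min(cells, key=cells.get)
        assert (model.metadata["kernel"], model.metadata["C"],
                model.metadata["gamma"]) == winner
        assert model.metadata["cv_rmse"] == pytest.approx(cells[winner], rel=1e-9)


class TestNeuralModels:
    def test_bpnn_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ np.arange(1.0, 9.0)
        kw = dict(hidden=16, epochs=25, n_restarts=2, seed=5)
        m1 = fit_bpnn(X[:30], y[:30], X[30:], y[30:], **kw)
        m2 = fit_bpnn(X[:30], y[:30], X[30:], y[30:], **kw)
        assert np.array_equal(m1.predict(X[30:]), m2.predict(X[30:]))

    def test_bpnn_learns_linear_target(self, rng):
        """Noiseless linear data: the network approaches the r = 1 of the
        least-squares oracle on held-out samples."""
        X = rng.normal(size=(192, 20))
        y = X @ np.linspace(0.5, 2.0, 20)
        m = fit_bpnn(X[:160], y[:160], X[160:], y[160:],
                     epochs=500, n_restarts=1, seed=0)
        r = np.corrcoef(m.predict(X[160:]), y[160:])[0, 1]
        assert r >= 0.99

    def test_bpnn_best_restart_bookkeeping(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ np.arange(1.0, 7.0)
        m = fit_bpnn(X[:30], y[:30], X[30:], y[30:],
                     hidden=8, epochs=20, n_restarts=3, seed=2)
        logged = [e["val_rmse"] for e in m.metadata["restarts"]]
        assert m.metadata["val_rmse"] == min(logged)

    def test_cnn_seeded_determinism_and_layer_registry(self, small_dataset):
        spectra, contents = small_dataset
        X, y = spectra.values, contents.prolamin
        kw = dict(epochs=10, n_restarts=1, seed=4, channels=(4, 8),
                  fc_sizes=(16, 8))
        m1 = fit_cnn(X[:50], y[:50], X[50:], y[50:], **kw)
        m2 = fit_cnn(X[:50], y[:50], X[50:], y[50:], **kw)
        assert np.array_equal(m1.predict(X[50:]), m2.predict(X[50:]))
        # conv2 activations: L2 = (60-7+1)//2 - 5 + 1 = 23 positions
        act = m1.estimator.conv_activation(m1._transform(X[:3]), "conv2")
        assert act.shape == (3, 8, 23)
        assert "conv2" in m1.estimator.layer_names

    def test_predict_shape_mismatch_names_both_sizes(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ np.arange(1.0, 9.0)
        m = fit_plsr(X, y, component_grid=[2], folds=3)
        with pytest.raises(ShapeError, match="8.*5|5.*8"):
            predict(m, rng.normal(size=(4, 5)))

    def test_predictions_invariant_to_row_order(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ np.arange(1.0, 9.0)
        m = fit_bpnn(X[:24], y[:24], X[24:], y[24:],
                     hidden=8, epochs=15, n_restarts=1, seed=1)
        Xt = rng.normal(size=(6, 8))
        perm = rng.permutation(6)
        direct = m.predict(Xt)
        permuted = m.predict(Xt[perm])
        assert np.allclose(direct[perm], permuted)
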