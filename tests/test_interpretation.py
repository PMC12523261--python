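import numpy as np
import pytest

from specgrain._nn import ConvNet1D
from specgrain.errors import ConfigError
from specgrain.feature_selection import WavelengthSelection, threshold_select
from specgrain.interpretation import (ImportanceProfile, gradcampp_map,
                                      gradcampp_profile, profile_to_ranges)
from specgrain.models import FittedModel, fit_cnn
from specgrain.synthetic import SpectraSet, WavelengthGrid


def _toy_net():
    """Small fixed-weight CNN kept away from ReLU kinks and pool ties so the
    network is locally smooth around the probe input."""
    rng = np.random.default_rng(0)
    net = ConvNet1D(12, rng, channels=(2, 1), kernels=(3, 3), fc_sizes=(4, 3))
    for name, w in net.state_dict().items():
        flat = 0.05 + 0.02 * np.arange(w.size).reshape(w.shape)
        net.load_state_dict({name: flat})
    return net


def _toy_input():
    return np.linspace(0.4, 1.6, 12)[None, :] ** 1.1


class TestGradCAMppMap:
    def test_toy_network_matches_central_difference_oracle(self):
        """dY/dA from the analytic backward pass — and the saliency map
        built from it — agree with central finite differences to 1e-4."""
        net = _toy_net()
        X = _toy_input()
        A, g = net.activation_and_gradient(X, "conv2")
        eps = 1e-6
        g_fd = np.zeros_like(A[0])
        for c in range(A.shape[1]):
            for l in range(A.shape[2]):
                up = A.copy()
                up[0, c, l] += eps
                dn = A.copy()
                dn[0, c, l] -= eps
                g_fd[c, l] = (net.forward_from(up, "conv2")[0]
                              - net.forward_from(dn, "conv2")[0]) / (2 * eps)
        assert np.abs(g_fd - g[0]).max() <= 1e-4
        m_exact = gradcampp_map(A[0], g[0])
        m_fd = gradcampp_map(A[0], g_fd)
        assert np.abs(m_exact - m_fd).max() <= 1e-4

    def test_map_nonnegative(self, rng):
        A = np.abs(rng.normal(size=(4, 9)))
        g = rng.normal(size=(4, 9))
        assert np.all(gradcampp_map(A, g) >= 0)

    def test_zero_gradient_gives_zero_map(self, rng):
        A = np.abs(rng.normal(size=(3, 7)))
        assert np.all(gradcampp_map(A, np.zeros_like(A)) == 0)

    def test_normalization_cancels_positive_map_scaling(self, rng):
        """Min-max normalization removes any positive constant multiplying
        the saliency map."""
        from specgrain.interpretation import _minmax_rows
        M = np.abs(rng.normal(size=(5, 20)))
        assert np.allclose(_minmax_rows(M), _minmax_rows(7.3 * M))


class TestGradCAMppProfile:
    @pytest.fixture(scope="class")
    def fitted(self, small_dataset):
        spectra, contents = small_dataset
        X, y = spectra.values, contents.prolamin
        model = fit_cnn(X[:50], y[:50], X[50:60], y[50:60],
                        epochs=60, n_restarts=1, seed=2,
                        channels=(4, 8), fc_sizes=(16, 8))
        return model, spectra

    def test_rows_normalized_to_unit_interval(self, fitted):
        model, spectra = fitted
        prof = gradcampp_profile(model, spectra.take_samples(range(60, 72)))
        assert prof.per_sample.min() >= 0 and prof.per_sample.max() <= 1
        row_max = prof.per_sample.max(axis=1)
        nonzero = prof.per_sample.any(axis=1)
        assert np.allclose(row_max[nonzero], 1.0)

    def test_mean_sd_are_column_statistics(self, fitted):
        model, spectra = fitted
        prof = gradcampp_profile(model, spectra.take_samples(range(60, 72)))
        assert np.allclose(prof.mean, prof.per_sample.mean(axis=0))
        assert np.allclose(prof.sd, prof.per_sample.std(axis=0, ddof=1))

    def test_constant_output_model_yields_zero_profile(self, fitted):
        model, spectra = fitted
        import copy
        frozen = copy.deepcopy(model)
        frozen.estimator.Wf3[...] = 0.0
        frozen.estimator.bf3[...] = 1.0
        prof = gradcampp_profile(frozen, spectra.take_samples(range(60, 66)))
        assert np.all(prof.per_sample == 0)
        assert np.all(prof.mean == 0)

    def test_unknown_layer_lists_available(self, fitted):
        model, spectra = fitted
        with pytest.raises(ConfigError, match="conv1.*conv2|conv2.*conv1"):
            gradcampp_profile(model, spectra.take_samples(range(3)),
                              layer="conv9")

    def test_non_cnn_model_rejected(self, small_dataset, rng):
        from specgrain.models import fit_plsr
        spectra, contents = small_dataset
        plsr = fit_plsr(spectra.values[:30], contents.prolamin[:30],
                        component_grid=[2], folds=3)
        with pytest.raises(ConfigError, match="CNN"):
            gradcampp_profile(plsr, spectra.take_samples(range(3)))

    def test_pooled_normalization_bounds(self, fitted):
        model, spectra = fitted
        prof = gradcampp_profile(model, spectra.take_samples(range(60, 72)),
                                 normalize="pooled")
        assert prof.per_sample.min() >= 0 and prof.per_sample.max() <= 1
        # pooled scaling: the global maximum is 1, rows need not reach it
        assert prof.per_sample.max() == pytest.approx(1.0)

    def test_abs_rectification_valid_and_relu_equivalent_for_positive_g(self, rng):
        A = np.abs(rng.normal(size=(4, 9)))
        g_pos = np.abs(rng.normal(size=(4, 9)))
        # with nonnegative gradients the two rectifications coincide
        assert np.allclose(gradcampp_map(A, g_pos, rectify="abs"),
                           gradcampp_map(A, g_pos, rectify="relu"))
        g = rng.normal(size=(4, 9))
        m = gradcampp_map(A, g, rectify="abs")
        assert np.all(m >= 0) and np.all(np.isfinite(m))

    def test_threshold_nesting_on_profile(self, fitted):
        model, spectra = fitted
        prof = gradcampp_profile(model, spectra.take_samples(range(60, 72)))
        hi = set(threshold_select(prof.mean, 0.7).indices.tolist())
        lo = set(threshold_select(prof.mean, 0.6).indices.tolist())
        assert hi <= lo


class TestProfileToRanges:
    def _grid(self, n=10):
        return WavelengthGrid(1000.0 + 10.0 * np.arange(n))

    def test_runs_grouped(self):
        sel = WavelengthSelection("GRADCAMPP", np.array([0, 1, 2, 6, 7]))
        ranges = profile_to_ranges(sel, self._grid())
        assert ranges == [(1000.0, 1020.0), (1060.0, 1070.0)]

    def test_single_index_degenerate_interval(self):
        sel = WavelengthSelection("GRADCAMPP", np.array([4]))
        assert profile_to_ranges(sel, self._grid()) == [(1040.0, 1040.0)]

    def test_empty_selection(self):
        sel = WavelengthSelection("GRADCAMPP", np.array([], dtype=int))
        assert profile_to_ranges(sel, self._grid()) == []
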