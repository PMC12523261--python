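import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

from specgrain.errors import ConfigError, FitError
from specgrain.preprocessing import (combined_retained, remove_outliers_plsr,
                                     split_dataset, trim_bands)
from specgrain.synthetic import ContentTable, SpectraSet, WavelengthGrid


def _spectra(values, start=900.0, step=3.0):
    values = np.asarray(values, dtype=float)
    grid = WavelengthGrid(start + step * np.arange(values.shape[1]))
    ids = tuple(f"S{i}" for i in range(values.shape[0]))
    return SpectraSet(values, grid, ids)


class TestTrimBands:
    def test_224_bands_minus_13_head_11_tail_gives_200(self, rng):
        spectra = _spectra(rng.normal(size=(4, 224)))
        trimmed = trim_bands(spectra, 13, 11)
        assert trimmed.n_bands == 200
        assert np.array_equal(trimmed.values, spectra.values[:, 13:213])
        assert np.array_equal(trimmed.grid.wavelengths,
                              spectra.grid.wavelengths[13:213])

    def test_zero_trim_is_identity(self, rng):
        spectra = _spectra(rng.normal(size=(3, 10)))
        trimmed = trim_bands(spectra, 0, 0)
        assert np.array_equal(trimmed.values, spectra.values)

    def test_index_arithmetic(self, rng):
        spectra = _spectra(rng.normal(size=(2, 10)))
        trimmed = trim_bands(spectra, 2, 3)
        # bands 3..7 in 1-based counting, i.e. indices 2..6
        assert trimmed.n_bands == 5
        assert np.array_equal(trimmed.values, spectra.values[:, 2:7])

    def test_overtrim_raises(self, rng):
        spectra = _spectra(rng.normal(size=(2, 10)))
        with pytest.raises(ConfigError):
            trim_bands(spectra, 6, 4)


class TestSplitDataset:
    def test_288_samples_give_192_48_48(self):
        assert split_dataset(288, (4, 1, 1), 0).sizes == (192, 48, 48)

    def test_minimal_case(self):
        assert split_dataset(6, (4, 1, 1), 0).sizes == (4, 1, 1)

    @given(n=st.integers(6, 500), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_property(self, n, seed):
        split = split_dataset(n, (4, 1, 1), seed)
        union = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
        assert len(np.unique(union)) == n == len(union)

    def test_reseeding_changes_membership_not_sizes(self):
        a = split_dataset(60, (4, 1, 1), 0)
        b = split_dataset(60, (4, 1, 1), 1)
        assert a.sizes == b.sizes
        assert not np.array_equal(a.train_idx, b.train_idx)
        c = split_dataset(60, (4, 1, 1), 0)
        assert np.array_equal(a.train_idx, c.train_idx)

    def test_too_few_samples_raises(self):
        with pytest.raises(ConfigError):
            split_dataset(5, (4, 1, 1), 0)


def _linear_dataset(rng, n=40, p=8, noise=0.02):
    X = rng.normal(size=(n, p))
    # small coefficients keep y strictly positive, so it stays exactly linear
    y = X @ np.linspace(0.02, 0.05, p) + rng.normal(0, noise, n) + 5.0
    ids = tuple(f"S{i}" for i in range(n))
    spectra = _spectra(X)
    contents = ContentTable(ids, y, np.abs(rng.normal(5, 1, n)))
    return spectra, contents


class TestOutlierRemoval:
    def test_perfect_fit_removes_nothing(self, rng):
        spectra, contents = _linear_dataset(rng, noise=0.0)
        report = remove_outliers_plsr(spectra, contents, "prolamin",
                                      n_components=8, k_sd=3.0)
        assert len(report.removed_idx) == 0
        assert np.allclose(report.residuals, 0, atol=1e-8)

    def test_shifted_sample_is_detected(self, rng):
        """Shifting one target by 10x the unshifted fit's residual SD puts
        that sample past the 3-SD screen (residual recomputed directly)."""
        spectra, contents = _linear_dataset(rng, noise=0.05)
        base = PLSRegression(n_components=8, scale=False)
        base.fit(spectra.values, contents.prolamin)
        resid_sd = (contents.prolamin
                    - base.predict(spectra.values).ravel()).std(ddof=1)
        shifted = contents.prolamin.copy()
        shifted[7] += 10 * resid_sd
        contents2 = ContentTable(contents.sample_ids, shifted, contents.glutelin)
        report = remove_outliers_plsr(spectra, contents2, "prolamin",
                                      n_components=8, k_sd=3.0)
        assert 7 in report.removed_idx

    def test_infinite_threshold_removes_nothing(self, rng):
        spectra, contents = _linear_dataset(rng, noise=0.5)
        report = remove_outliers_plsr(spectra, contents, "prolamin",
                                      n_components=5, k_sd=np.inf)
        assert len(report.removed_idx) == 0
        assert len(report.retained_idx) == spectra.n_samples

    def test_zero_variance_spectra_raise(self):
        grid = WavelengthGrid(900 + 3.0 * np.arange(5))
        spectra = SpectraSet(np.ones((20, 5)), grid,
                             tuple(f"S{i}" for i in range(20)))
        contents = ContentTable(spectra.sample_ids,
                                np.linspace(0.5, 0.9, 20),
                                np.linspace(3.5, 7.0, 20))
        with pytest.raises(FitError):
            remove_outliers_plsr(spectra, contents, "prolamin", n_components=2)

    def test_idempotent_on_clean_data(self, rng):
        spectra, contents = _linear_dataset(rng, noise=0.0)
        first = remove_outliers_plsr(spectra, contents, "prolamin",
                                     n_components=8)
        sub_s = spectra.take_samples(first.retained_idx)
        sub_c = contents.take(first.retained_idx)
        second = remove_outliers_plsr(sub_s, sub_c, "prolamin", n_components=8)
        assert len(second.removed_idx) == 0

    def test_combined_retained_intersects(self, rng):
        spectra, contents = _linear_dataset(rng, noise=0.05)

        class Fake:
            def __init__(self, retained):
                self.retained_idx = np.array(retained)

        combined = combined_retained([Fake([0, 1, 2, 3]), Fake([1, 2, 3, 9])])
        assert combined.tolist() == [1, 2, 3]
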