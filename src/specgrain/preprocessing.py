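"""Band trimming, PLSR-residual outlier screening, and dataset partitioning.

The acquisition workflow drops noisy edge bands before analysis (13 leading
bands below 980 nm, 11 trailing bands above 1684 nm, leaving 200), screens
extreme samples by the residuals of a PLSR fit on all samples, and splits the
retained samples into training/validation/test sets at a 4:1:1 ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .errors import ConfigError, FitError
from .synthetic import ContentTable, SpectraSet

__all__ = [
    "SplitAssignment",
    "OutlierReport",
    "trim_bands",
    "remove_outliers_plsr",
    "combined_retained",
    "split_dataset",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/validation/test index sets covering all samples."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    ratio: tuple

    def __post_init__(self):
        tr = np.asarray(self.train_idx, dtype=int)
        va = np.asarray(self.val_idx, dtype=int)
        te = np.asarray(self.test_idx, dtype=int)
        union = np.concatenate([tr, va, te])
        if len(np.unique(union)) != len(union):
            raise ConfigError("split index sets must be pairwise disjoint")
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "val_idx", va)
        object.__setattr__(self, "test_idx", te)

    @property
    def sizes(self) -> tuple:
        return (len(self.train_idx), len(self.val_idx), len(self.test_idx))

    @property
    def n_samples(self) -> int:
        return sum(self.sizes)

    def to_dict(self) -> dict:
        return {
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "seed": int(self.seed),
            "ratio": list(self.ratio),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["train_idx"]), np.array(d["val_idx"]),
                   np.array(d["test_idx"]), d["seed"], tuple(d["ratio"]))


@dataclass(frozen=True)
class OutlierReport:
    """Outcome of one PLSR-residual outlier screen (single analyte)."""

    analyte: str
    retained_idx: np.ndarray
    removed_idx: np.ndarray
    residuals: np.ndarray   # measured - predicted, content %
    threshold: float        # k_sd * SD(residuals), content %
    k_sd: float
    n_components: int

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "retained_idx": np.asarray(self.retained_idx).tolist(),
            "removed_idx": np.asarray(self.removed_idx).tolist(),
            "residuals": np.asarray(self.residuals).tolist(),
            "threshold": float(self.threshold),
            "k_sd": float(self.k_sd),
            "n_components": int(self.n_components),
        }


def trim_bands(spectra: SpectraSet, n_head: int, n_tail: int) -> SpectraSet:
    """Drop ``n_head`` leading and ``n_tail`` trailing bands (pure slicing)."""
    if n_head < 0 or n_tail < 0:
        raise ConfigError("n_head and n_tail must be >= 0")
    if n_head + n_tail >= spectra.n_bands:
        raise ConfigError(
            f"cannot trim {n_head}+{n_tail} bands from a {spectra.n_bands}-band set"
        )
    stop = spectra.n_bands - n_tail
    return spectra.take_bands(np.arange(n_head, stop))


def remove_outliers_plsr(
    spectra: SpectraSet,
    contents: ContentTable,
    analyte: str,
    n_components: int = 10,
    k_sd: float = 3.0,
) -> OutlierReport:
    """Screen samples whose PLSR prediction error is extreme.

    A single PLSR model is fitted on *all* samples; samples with
    ``|measured - predicted| > k_sd * SD(residuals)`` are flagged for removal.
    One pass, no iteration.
    """
    X = spectra.values
    y = contents.values(analyte)
    if len(y) != spectra.n_samples:
        raise ConfigError("contents and spectra must have the same sample count")
    if spectra.n_samples < n_components + 2:
        raise ConfigError(
            f"need >= {n_components + 2} samples for {n_components} PLSR components"
        )
    if np.allclose(X.std(axis=0), 0):
        raise FitError("degenerate spectra: all bands have zero variance")
    if np.std(y) == 0:
        raise FitError("degenerate contents: zero variance")
    ncomp = min(n_components, spectra.n_samples - 1, spectra.n_bands)
    model = PLSRegression(n_components=ncomp, scale=False)
    model.fit(X, y)
    residuals = y - model.predict(X).ravel()
    sd = float(residuals.std(ddof=1))
    threshold = k_sd * sd
    if sd <= 1e-10 * float(np.std(y)):
        # perfect fit up to round-off: nothing to screen
        removed = np.array([], dtype=int)
    else:
        removed = np.flatnonzero(np.abs(residuals) > threshold)
    retained = np.setdiff1d(np.arange(len(y)), removed)
    return OutlierReport(analyte, retained, removed, residuals,
                         threshold, k_sd, ncomp)


def combined_retained(reports) -> np.ndarray:
    """Samples retained by *every* report (removal for either analyte removes
    the sample for both, so one common dataset serves both calibrations)."""
    retained = None
    for rep in reports:
        s = set(np.asarray(rep.retained_idx).tolist())
        retained = s if retained is None else retained & s
    return np.array(sorted(retained), dtype=int)


def split_dataset(n_samples: int, ratio=(4, 1, 1), seed: int = 0) -> SplitAssignment:
    """Seeded random partition into train/validation/test at the given ratio.

    Sizes are floor-proportional for validation and test, with the remainder
    assigned to training; 288 samples at 4:1:1 give (192, 48, 48).
    """
    ratio = tuple(int(r) for r in ratio)
    if len(ratio) != 3 or any(r <= 0 for r in ratio):
        raise ConfigError("ratio must be three positive integers")
    total = sum(ratio)
    if n_samples < total:
        raise ConfigError(f"need >= {total} samples for a {ratio} split, got {n_samples}")
    n_val = n_samples * ratio[1] // total
    n_test = n_samples * ratio[2] // total
    n_train = n_samples - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n_samples)
    return SplitAssignment(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train:n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val:]),
        seed=seed,
        ratio=ratio,
    )
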