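"""Grad-CAM++ saliency for 1-D regression CNNs.

Grad-CAM++ attributes a network's scalar output Y to the positions of a
convolutional feature map A. With g = dY/dA, the per-position fusing
coefficients are

    alpha = g^2 / (2 g^2 + sum_positions(A) * g^3)        (0/0 := 0)

computed elementwise per channel; channel weights are
``w_k = sum_positions(alpha * relu(g))`` and the saliency map is
``M = relu(sum_k w_k A_k)``. Exact second/third derivatives of a
ReLU network's output vanish almost everywhere, so the standard surrogate
replaces them by elementwise ``g^2`` and ``g^3`` (exact under an exponential
transform of the score); the regression output is used directly, as no class
score exists.

Maps are interpolated from layer positions to the wavelength grid and
min–max normalized to [0, 1] per sample; the mean and SD across samples give
the wavelength-importance profile used for threshold-based feature
selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .feature_selection import WavelengthSelection
from .synthetic import SpectraSet, WavelengthGrid

__all__ = ["ImportanceProfile", "gradcampp_profile", "gradcampp_map",
           "profile_to_ranges"]


@dataclass(frozen=True)
class ImportanceProfile:
    """Per-sample normalized wavelength-importance weights and their
    per-wavelength mean and (sample) SD."""

    per_sample: np.ndarray   # n_samples x n_bands, each row in [0, 1]
    mean: np.ndarray
    sd: np.ndarray
    layer_name: str
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.per_sample, dtype=float)
        if w.ndim != 2:
            raise ConfigError("per_sample must be 2-D")
        if np.any(w < 0) or np.any(w > 1):
            raise ConfigError("per-sample weights must lie in [0, 1]")
        object.__setattr__(self, "per_sample", w)
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))

    @classmethod
    def from_maps(cls, maps: np.ndarray, layer_name: str,
                  wavelengths_nm=None) -> "ImportanceProfile":
        maps = np.asarray(maps, dtype=float)
        return cls(maps, maps.mean(axis=0), maps.std(axis=0, ddof=1),
                   layer_name, wavelengths_nm)

    def to_dict(self) -> dict:
        return {
            "layer_name": self.layer_name,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "wavelengths_nm": None if self.wavelengths_nm is None
            else np.asarray(self.wavelengths_nm).tolist(),
            "n_samples": int(self.per_sample.shape[0]),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _minmax_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise min–max to [0, 1]; all-zero rows stay zero, constant
    positive rows map to 1 (the maximum of any nonzero row is 1)."""
    out = np.zeros_like(M)
    lo = M.min(axis=1, keepdims=True)
    hi = M.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span.ravel() == 0
    nz_flat = flat & (hi.ravel() > 0)
    out[nz_flat] = 1.0
    ok = ~flat
    out[ok] = (M[ok] - lo[ok]) / span[ok]
    return out


def gradcampp_map(A: np.ndarray, g: np.ndarray,
                  rectify: str = "relu") -> np.ndarray:
    """Raw (unnormalized) Grad-CAM++ saliency over layer positions.

    ``A`` and ``g`` are (channels, positions) feature maps and gradients for
    one sample. ``rectify="relu"`` keeps content-increasing evidence only;
    ``"abs"`` weighs evidence in both directions. The result is nonnegative
    by the final ReLU.
    """
    if rectify not in ("relu", "abs"):
        raise ConfigError("rectify must be 'relu' or 'abs'")
    A = np.asarray(A, dtype=float)
    g = np.asarray(g, dtype=float)
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + A.sum(axis=1, keepdims=True) * g3
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(denom != 0, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    rect = np.maximum(g, 0.0) if rectify == "relu" else np.abs(g)
    w = (alpha * rect).sum(axis=1)
    return np.maximum(w @ A, 0.0)


def gradcampp_profile(
    model,
    samples: SpectraSet,
    layer: str = "conv2",
    interpolation: str = "linear",
    rectify: str = "relu",
    normalize: str = "per_sample",
) -> ImportanceProfile:
    """Grad-CAM++ importance profile of a fitted CNN over a sample set.

    For every sample the saliency map over the named conv layer's positions
    is computed, interpolated to the wavelength grid (linear by default,
    ``"nearest"`` available) and min–max normalized to [0, 1] — per sample
    by default, or over the pooled sample set (``normalize="pooled"``); the
    profile aggregates the per-sample maps into a per-wavelength mean and
    SD.
    """
    if getattr(model, "family", None) != "CNN":
        raise ConfigError(f"Grad-CAM++ needs a CNN model, got {getattr(model, 'family', type(model))}")
    if samples.n_bands != model.n_bands:
        raise ConfigError(
            f"samples have {samples.n_bands} bands but the model expects {model.n_bands}"
        )
    if interpolation not in ("linear", "nearest"):
        raise ConfigError("interpolation must be 'linear' or 'nearest'")
    if normalize not in ("per_sample", "pooled"):
        raise ConfigError("normalize must be 'per_sample' or 'pooled'")
    net = model.estimator
    X = model._transform(samples.values)
    A, g = net.activation_and_gradient(X, layer)   # (B, C, L)

    n_bands = samples.n_bands
    L = A.shape[2]
    pos = np.linspace(0.0, 1.0, L)
    tgt = np.linspace(0.0, 1.0, n_bands)
    maps = np.empty((len(X), n_bands))
    for i in range(len(X)):
        m = gradcampp_map(A[i], g[i], rectify=rectify)
        if interpolation == "linear":
            maps[i] = np.interp(tgt, pos, m)
        else:
            maps[i] = m[np.argmin(np.abs(tgt[:, None] - pos[None, :]), axis=1)]
    if normalize == "per_sample":
        maps = _minmax_rows(maps)
    else:
        lo, hi = maps.min(), maps.max()
        maps = (maps - lo) / (hi - lo) if hi > lo else np.zeros_like(maps)
    return ImportanceProfile.from_maps(maps, layer,
                                       samples.grid.wavelengths.copy())


def profile_to_ranges(selection: WavelengthSelection,
                      grid: WavelengthGrid) -> list:
    """Maximal runs of consecutive selected indices as (first nm, last nm)."""
    idx = np.asarray(selection.indices, dtype=int)
    if len(idx) == 0:
        return []
    if np.any(idx >= len(grid)):
        raise ConfigError("selection indices exceed the grid length")
    wl = grid.wavelengths
    ranges = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            ranges.append((float(wl[run_start]), float(wl[prev])))
            run_start = i
        prev = i
    ranges.append((float(wl[run_start]), float(wl[prev])))
    return ranges
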