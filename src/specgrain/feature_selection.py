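"""Feature-wavelength selection: SPA, CARS, and importance thresholding.

Three routes to a reduced wavelength set:

* **SPA** (successive projections algorithm) — greedy chains that minimize
  collinearity: each step picks the column with maximal residual norm after
  orthogonal projection onto the complement of the span of the columns
  already chosen; candidate subsets are scored by ordinary-least-squares RMSE
  on a held-out validation split.
* **CARS** (competitive adaptive reweighted sampling) — Monte Carlo PLSR
  fits on row subsamples, an exponentially decreasing retention schedule, and
  adaptive reweighted sampling driven by |regression coefficient|; the run
  whose retained set has minimal cross-validated RMSE on the training set
  wins.
* **threshold_select** — keep wavelengths whose mean importance weight
  (e.g. a Grad-CAM++ profile) strictly exceeds a threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._pls import loo_rmse_by_components, pls1_coefficients
from .errors import ConfigError, SelectionError

__all__ = [
    "WavelengthSelection",
    "spa_select",
    "spa_chain",
    "cars_select",
    "cars_schedule",
    "threshold_select",
]


@dataclass(frozen=True)
class WavelengthSelection:
    """An ordered subset of band indices with provenance."""

    method: str                      # SPA | CARS | GRADCAMPP | FULL
    indices: np.ndarray              # ascending, unique band indices
    wavelengths_nm: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    score: float | None = None       # internal validation RMSE (SPA/CARS)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ConfigError("selection indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ConfigError("selection indices must be unique")
        if np.any(idx < 0):
            raise ConfigError("selection indices must be nonnegative")
        object.__setattr__(self, "indices", np.sort(idx))
        if self.wavelengths_nm is not None:
            wl = np.asarray(self.wavelengths_nm, dtype=float)
            if wl.shape != idx.shape:
                raise ConfigError("wavelengths_nm must match indices in length")
            object.__setattr__(self, "wavelengths_nm", np.sort(wl))

    def __len__(self) -> int:
        return len(self.indices)

    def nm_line(self) -> str:
        """Comma-separated nm list, the format used in selection reports."""
        if self.wavelengths_nm is None:
            return ", ".join(str(i) for i in self.indices)
        return ", ".join(f"{w:.0f}" for w in self.wavelengths_nm)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "indices": self.indices.tolist(),
            "wavelengths_nm": None if self.wavelengths_nm is None
            else self.wavelengths_nm.tolist(),
            "params": self.params,
            "score": self.score,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WavelengthSelection":
        with open(path) as fh:
            d = json.load(fh)
        wl = d.get("wavelengths_nm")
        return cls(d["method"], np.array(d["indices"], dtype=int),
                   None if wl is None else np.array(wl, dtype=float),
                   d.get("params", {}), d.get("score"))


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start: int, n_max: int, rel_tol: float = 1e-9):
    """Projection chain from a start column (columns assumed centered).

    Returns the chain (list of column indices, length <= n_max); stops early
    when every remaining projected norm falls below ``rel_tol`` times the
    largest original column norm (numerical dependence).
    """
    R = np.array(X, dtype=float, copy=True)
    n, p = R.shape
    norm_scale = np.linalg.norm(R, axis=0).max()
    chain = [start]
    available = np.ones(p, dtype=bool)
    available[start] = False
    for _ in range(1, min(n_max, p)):
        u = R[:, chain[-1]]
        uu = u @ u
        if uu <= (rel_tol * norm_scale) ** 2:
            break
        R = R - np.outer(u, u @ R) / uu
        norms = np.linalg.norm(R, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))   # argmax breaks ties by lower index
        if norms[nxt] <= rel_tol * norm_scale:
            break
        chain.append(nxt)
        available[nxt] = False
    return chain


def _ols_val_rmse(X_train, y_train, X_val, y_val, cols) -> float:
    A = np.column_stack([np.ones(len(X_train)), X_train[:, cols]])
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    Av = np.column_stack([np.ones(len(X_val)), X_val[:, cols]])
    resid = Av @ coef - y_val
    return float(np.sqrt(np.mean(resid ** 2)))


def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_min: int = 30,
    n_max: int = 50,
    wavelengths: np.ndarray | None = None,
) -> WavelengthSelection:
    """SPA wavelength selection scored on a held-out validation split.

    Chains are grown from every start column on training-mean-centered data;
    each candidate subset (chain prefix of size in ``[n_min, n_max]``) is
    scored by the validation RMSE of an ordinary-least-squares fit on the
    selected columns. Ties prefer the smaller subset, then lexicographically
    smaller index tuples.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    n, p = X_train.shape
    if not (1 <= n_min <= n_max):
        raise ConfigError("require 1 <= n_min <= n_max")
    if n_max >= min(p, n):
        raise ConfigError(
            f"n_max={n_max} must be < min(n_bands={p}, n_train={n})"
        )
    Xc = X_train - X_train.mean(axis=0)

    best = None  # (rmse, size, tuple(sorted idx), chain prefix)
    longest = 0
    for start in range(p):
        chain = spa_chain(Xc, start, n_max)
        longest = max(longest, len(chain))
        if len(chain) < n_min:
            continue
        for m in range(n_min, min(n_max, len(chain)) + 1):
            cols = sorted(chain[:m])
            rmse = _ols_val_rmse(X_train, y_train, X_val, y_val, cols)
            key = (rmse, m, tuple(cols))
            if best is None or key < best:
                best = key
    if best is None:
        raise SelectionError(
            f"columns became numerically dependent at chain length {longest}, "
            f"before n_min={n_min} was reached"
        )
    rmse, m, cols = best
    idx = np.array(cols, dtype=int)
    return WavelengthSelection(
        method="SPA",
        indices=idx,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[idx],
        params={"n_min": n_min, "n_max": n_max},
        score=rmse,
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def cars_schedule(p: int, n_runs: int) -> np.ndarray:
    """Retained-count schedule: ceil(r_i * p) with r_i = a * exp(-k*i).

    The decay constants are anchored so the first run retains all ``p``
    columns and the last retains exactly 2:  k = ln(p/2)/(N-1), a = e^k.
    """
    if n_runs < 2:
        raise ConfigError("n_runs must be >= 2")
    if p <= 2:
        raise ConfigError("need more than 2 columns for a CARS schedule")
    k = math.log(p / 2.0) / (n_runs - 1)
    i = np.arange(n_runs)
    r = np.exp(-k * i)           # a*e^(-k*i) with 1-based i and a = e^k
    counts = np.ceil(r * p - 1e-9).astype(int)
    counts[0] = p
    counts[-1] = 2
    return counts


def _cv_rmse(X, y, max_components, cv) -> float:
    """Minimal CV RMSE over component counts; cv='loo' or a fold count."""
    n = len(y)
    if cv == "loo":
        return float(loo_rmse_by_components(X, y, max_components).min())
    folds = int(cv)
    A = int(min(max_components, n - math.ceil(n / folds) - 1, X.shape[1]))
    if A < 1:
        raise SelectionError("too few samples for the requested CV folds")
    order = np.arange(n)
    sq = np.zeros(A)
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        B, c = pls1_coefficients(X[train], y[train], A)
        pred = X[test] @ B.T + c
        sq += ((pred - y[test, None]) ** 2).sum(axis=0)
    return float(np.sqrt(sq / n).min())


def cars_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_runs: int = 5000,
    max_components: int = 20,
    mc_fraction: float = 0.8,
    seed: int = 0,
    cv="loo",
    wavelengths: np.ndarray | None = None,
) -> WavelengthSelection:
    """CARS wavelength selection.

    At run *i* a PLSR is fitted on a Monte Carlo row subsample restricted to
    the currently retained columns (component count chosen by leave-one-out
    RMSE on the subsample, capped at ``max_components``); columns are then
    competitively reduced to the schedule count ``ceil(r_i * p)`` by weighted
    sampling without replacement with probability proportional to the
    normalized |regression coefficient|. After all runs, each run's retained
    set is scored by cross-validated PLSR RMSE on the full training set and
    the minimum wins (ties: fewer columns, then the earlier run).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    n, p = X_train.shape
    if max_components >= n:
        raise ConfigError("max_components must be < n_train")
    counts = cars_schedule(p, n_runs)
    rng = np.random.default_rng(seed)
    n_sub = max(2, math.ceil(mc_fraction * n))

    retained = np.arange(p)
    history = []
    for i in range(n_runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        Xs = X_train[np.ix_(rows, retained)]
        ys = y_train[rows]
        A = int(min(max_components, n_sub - 2, len(retained)))
        if A < 1 or len(retained) < 2:
            raise SelectionError(
                f"retained set collapsed to {len(retained)} usable columns at run {i + 1}"
            )
        loo = loo_rmse_by_components(Xs, ys, A)
        a_best = int(np.argmin(loo)) + 1
        B, _ = pls1_coefficients(Xs, ys, a_best)
        weights = np.abs(B[a_best - 1])

        n_keep = min(counts[i], len(retained))
        if n_keep < len(retained):
            w = weights + 1e-12 * weights.max(initial=1.0)  # keep probs valid
            probs = w / w.sum()
            keep_local = rng.choice(len(retained), size=n_keep,
                                    replace=False, p=probs)
            retained = np.sort(retained[keep_local])
        history.append(retained.copy())

    scored = {}
    results = []
    for i, subset in enumerate(history):
        key = tuple(subset.tolist())
        if key not in scored:
            scored[key] = _cv_rmse(X_train[:, subset], y_train,
                                   min(max_components, len(subset)), cv)
        results.append((scored[key], len(subset), i))
    rmse, size, run = min(results)
    idx = history[run]
    return WavelengthSelection(
        method="CARS",
        indices=idx,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[idx],
        params={
            "n_runs": n_runs,
            "retained_counts": [len(h) for h in history],
            "max_components": max_components,
            "mc_fraction": mc_fraction,
            "seed": seed,
            "cv": cv,
            "winning_run": run + 1,
        },
        score=rmse,
    )


# ---------------------------------------------------------------------------
# Importance thresholding
# ---------------------------------------------------------------------------

def threshold_select(
    profile_mean: np.ndarray,
    threshold: float,
    wavelengths: np.ndarray | None = None,
) -> WavelengthSelection:
    """Keep wavelengths whose mean importance weight strictly exceeds
    ``threshold``; an empty result is valid."""
    mean = np.asarray(profile_mean, dtype=float)
    if mean.ndim != 1:
        raise ConfigError("profile_mean must be 1-D")
    if not np.all(np.isfinite(mean)):
        raise ConfigError("profile_mean must be finite")
    idx = np.flatnonzero(mean > threshold)
    return WavelengthSelection(
        method="GRADCAMPP",
        indices=idx,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[idx],
        params={"threshold": threshold, "empty": bool(len(idx) == 0)},
    )
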