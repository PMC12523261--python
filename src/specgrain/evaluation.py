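"""Evaluation metrics and report tables.

Model quality is summarized per split by the Pearson correlation between
measured and predicted contents (r_c / r_v / r_p on the training, validation
and test sets) and the root-mean-square error (RMSEC / RMSEV / RMSEP, in
content %). Wavelength selections are additionally accounted for by their
variable-reduction percentage relative to the full spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, MetricError, ShapeError

__all__ = ["EvaluationReport", "pearson_r", "rmse", "evaluate",
           "reduction_report", "scatter_data", "render_table"]

SPLITS = ("training", "validation", "test")


def pearson_r(y, y_pred) -> float:
    """Sample Pearson correlation between measured and predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ShapeError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if len(y) < 2:
        raise MetricError("need at least 2 points for a correlation")
    if np.std(y) == 0 or np.std(y_pred) == 0:
        raise MetricError("correlation undefined: zero variance input")
    return float(stats.pearsonr(y, y_pred).statistic)


def rmse(y, y_pred) -> float:
    """Root-mean-square error in the units of y (content %)."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ShapeError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if len(y) == 0:
        raise ShapeError("need at least one point")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-split r / RMSE for one (model, analyte, feature set)."""

    model_family: str
    analyte: str
    metrics: dict                 # split -> {"r": ..., "rmse": ...}
    selection_method: str = "FULL"
    n_selected: int | None = None
    n_full: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for split, m in self.metrics.items():
            if split not in SPLITS:
                raise ConfigError(f"unknown split {split!r}")
            if not -1.0 <= m["r"] <= 1.0 or m["rmse"] < 0:
                raise ConfigError("metrics out of range")

    @property
    def reduction_pct(self) -> float | None:
        if self.n_selected is None or not self.n_full:
            return None
        return reduction_report(self.n_selected, self.n_full)

    def to_dict(self) -> dict:
        return {
            "model_family": self.model_family,
            "analyte": self.analyte,
            "selection_method": self.selection_method,
            "n_selected": self.n_selected,
            "n_full": self.n_full,
            "reduction_pct": self.reduction_pct,
            "metrics": self.metrics,
            "extra": self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate(model, spectra, contents, analyte: str, split,
             selection=None, n_full: int | None = None) -> EvaluationReport:
    """Predict each split of a dataset and compute r / RMSE for it.

    ``spectra`` must already be restricted to the model's input bands (apply
    the selection with ``SpectraSet.take_bands`` first); ``split`` is a
    SplitAssignment over the same samples.
    """
    metrics = {}
    for name, idx in zip(SPLITS, (split.train_idx, split.val_idx, split.test_idx)):
        if len(idx) == 0:
            raise ConfigError(f"empty {name} split")
        X = spectra.values[idx]
        y = contents.values(analyte)[idx]
        pred = model.predict(X)
        metrics[name] = {"r": pearson_r(y, pred), "rmse": rmse(y, pred)}
    return EvaluationReport(
        model_family=model.family,
        analyte=analyte,
        metrics=metrics,
        selection_method="FULL" if selection is None else selection.method,
        n_selected=spectra.n_bands if selection is None else len(selection),
        n_full=n_full if n_full is not None else spectra.n_bands,
    )


def reduction_report(n_selected: int, n_full: int) -> float:
    """Variable-reduction percentage: 100 * (1 - n_selected / n_full)."""
    if n_full <= 0 or not 0 <= n_selected <= n_full:
        raise ConfigError(f"invalid counts: {n_selected} of {n_full}")
    return 100.0 * (1.0 - n_selected / n_full)


def scatter_data(y, y_pred):
    """(measured, predicted) pairs plus the least-squares fit line.

    Returns ``(pairs, slope, intercept)`` where ``pairs`` is an (n, 2) array;
    the fit line is predicted = slope * measured + intercept, by ordinary
    least squares. This is the plot-ready content of a measured-vs-predicted
    scatter figure.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ShapeError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if np.std(y) == 0:
        raise MetricError("fit line undefined: zero variance in measured values")
    A = np.column_stack([y, np.ones(len(y))])
    (slope, intercept), *_ = np.linalg.lstsq(A, y_pred, rcond=None)
    return np.column_stack([y, y_pred]), float(slope), float(intercept)


def render_table(reports) -> str:
    """Aligned-text table with r/RMSE per split, values to 3 decimals."""
    header = (f"{'Model':<6} {'Label':<9} {'Set':<7} "
              f"{'r_c':>6} {'RMSEC':>7} {'r_v':>6} {'RMSEV':>7} "
              f"{'r_p':>6} {'RMSEP':>7}")
    lines = [header]
    for rep in reports:
        m = rep.metrics
        sel = rep.selection_method
        lines.append(
            f"{rep.model_family:<6} {rep.analyte:<9} {sel:<7} "
            f"{m['training']['r']:>6.3f} {m['training']['rmse']:>7.3f} "
            f"{m['validation']['r']:>6.3f} {m['validation']['rmse']:>7.3f} "
            f"{m['test']['r']:>6.3f} {m['test']['rmse']:>7.3f}"
        )
    return "\n".join(lines)
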