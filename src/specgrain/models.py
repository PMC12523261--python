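"""Calibration models: PLSR, SVR, BPNN, and a 1-D CNN.

All fitters return a :class:`FittedModel` whose ``predict`` path checks the
band count against the fitted input size. PLSR and SVR are tuned by grid
search with 10-fold cross-validated RMSE (components 1–20 for PLSR; kernel /
C in 1e-7..1e7 / gamma mode for SVR). The neural models are trained with
Adam on mean-squared-error loss and the best of several seeded restarts
(minimal validation RMSE) is kept.

Feature scaling: PLSR is mean-centered only; SVR and BPNN standardize each
band by training statistics; the CNN centers per band but scales by a single
global factor so relative band amplitudes (and hence saliency) survive. The
neural models also standardize the target. All statistics are training-set
only and recorded on the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._nn import ConvNet1D, MLPRegressorNet, train_net
from .errors import ConfigError, FitError, ShapeError

__all__ = ["FittedModel", "fit_plsr", "fit_svr", "fit_bpnn", "fit_cnn", "predict"]

FAMILIES = ("PLSR", "SVR", "BPNN", "CNN")


@dataclass
class FittedModel:
    """A fitted calibration model plus its training metadata."""

    family: str
    estimator: object            # sklearn estimator or a _nn network
    n_bands: int
    metadata: dict = field(default_factory=dict)
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_bands:
            got = X.shape[1] if X.ndim == 2 else X.shape
            raise ShapeError(
                f"model was fitted on {self.n_bands} bands but input has {got}"
            )
        if self.family in ("PLSR", "SVR"):
            return np.asarray(self.estimator.predict(X)).ravel()
        out = self.estimator.forward(self._transform(X))
        return out * self.y_scale + self.y_mean


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(X)


def _check_xy(X, y, allow_constant=True):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ShapeError(f"X {X.shape} and y {y.shape} are inconsistent")
    if not allow_constant and np.std(y) == 0:
        raise FitError("zero-variance target: the calibration is undefined")
    return X, y


def fit_plsr(X, y, component_grid=None, folds: int = 10) -> FittedModel:
    """PLSR with the latent-factor count chosen by 10-fold CV RMSE.

    The candidate grid defaults to 1..20 and is clipped to what the fold
    sizes and band count allow; the winner is refit on all training rows.
    """
    X, y = _check_xy(X, y, allow_constant=False)
    n, p = X.shape
    if n <= folds:
        raise ConfigError(f"need more than folds={folds} samples, got {n}")
    max_allowed = min(p, n - (n // folds) - 1)
    if component_grid is None:
        component_grid = range(1, 21)
    grid = [c for c in component_grid if 1 <= c <= max_allowed]
    if not grid:
        raise ConfigError(
            f"component grid {list(component_grid)} has no entry <= {max_allowed}"
        )
    search = GridSearchCV(
        PLSRegression(scale=False),
        {"n_components": grid},
        scoring="neg_root_mean_squared_error",
        cv=KFold(n_splits=folds),
    )
    search.fit(X, y)
    return FittedModel(
        family="PLSR",
        estimator=search.best_estimator_,
        n_bands=p,
        metadata={
            "n_components": int(search.best_params_["n_components"]),
            "cv_rmse": float(-search.best_score_),
            "folds": folds,
        },
    )


def fit_svr(
    X,
    y,
    kernels=("linear", "rbf", "poly"),
    C_grid=None,
    gamma_modes=("scale", "auto"),
    folds: int = 10,
    max_iter: int = -1,
) -> FittedModel:
    """Epsilon-SVR with exhaustive (kernel, C, gamma-mode) grid search.

    C spans 1e-7..1e7 by default; features are standardized by training
    statistics inside the pipeline; scoring is 10-fold CV RMSE. libsvm can
    converge very slowly in the extreme-C cells, so ``max_iter`` offers an
    optional solver-iteration cap (-1 = unbounded).
    """
    X, y = _check_xy(X, y)
    if C_grid is None:
        C_grid = np.logspace(-7, 7, 15)
    C_grid = list(np.asarray(C_grid, dtype=float))
    if not (len(kernels) and len(C_grid) and len(gamma_modes)):
        raise ConfigError("kernels, C_grid and gamma_modes must be nonempty")
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(max_iter=max_iter))])
    search = GridSearchCV(
        pipe,
        {"svr__kernel": list(kernels), "svr__C": C_grid,
         "svr__gamma": list(gamma_modes)},
        scoring="neg_root_mean_squared_error",
        cv=KFold(n_splits=min(folds, len(y))),
        error_score="raise",
    )
    search.fit(X, y)
    best = search.best_params_
    return FittedModel(
        family="SVR",
        estimator=search.best_estimator_,
        n_bands=X.shape[1],
        metadata={
            "kernel": best["svr__kernel"],
            "C": float(best["svr__C"]),
            "gamma": best["svr__gamma"],
            "cv_rmse": float(-search.best_score_),
            "folds": folds,
        },
    )


def _standardize_train(X, y, per_band=True):
    """Training-statistics scaling.

    Per-band standardization suits the BPNN (each input is an independent
    feature). The CNN instead centers per band but scales by a single global
    factor (the mean per-band SD): dividing every band by its own SD would
    amplify noise in signal-free regions to unit variance, which both hurts
    the convolutional fit and makes activation-based saliency highlight
    uninformative regions.
    """
    x_mean = X.mean(axis=0)
    if per_band:
        x_scale = X.std(axis=0)
        x_scale[x_scale == 0] = 1.0
    else:
        scale = float(X.std(axis=0).mean()) or 1.0
        x_scale = np.full(X.shape[1], scale)
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    return (X - x_mean) / x_scale, (y - y_mean) / y_scale, x_mean, x_scale, y_mean, y_scale


def _fit_restarts(build, X, y, X_val, y_val, epochs, batch_size, lr,
                  n_restarts, seed, per_band=True):
    """Train ``n_restarts`` seeded networks; keep the lowest validation RMSE."""
    Xs, ys, x_mean, x_scale, y_mean, y_scale = _standardize_train(X, y, per_band)
    Xv = (np.asarray(X_val, dtype=float) - x_mean) / x_scale
    yv = np.asarray(y_val, dtype=float).ravel()
    best = None
    log = []
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        net = build(rng)
        curve = train_net(net, Xs, ys, epochs, batch_size, lr, rng)
        pred_val = net.forward(Xv) * y_scale + y_mean
        val_rmse = float(np.sqrt(np.mean((pred_val - yv) ** 2)))
        log.append({"restart": r, "val_rmse": val_rmse,
                    "final_train_loss": float(curve[-1])})
        if best is None or val_rmse < best[0]:
            best = (val_rmse, net, curve)
    val_rmse, net, curve = best
    return net, curve, log, val_rmse, (x_mean, x_scale, y_mean, y_scale)


def fit_bpnn(
    X,
    y,
    X_val,
    y_val,
    hidden: int = 1024,
    epochs: int = 5000,
    batch_size: int = 16,
    lr: float = 1e-3,
    n_restarts: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Single-hidden-layer ReLU network (BPNN), best of seeded restarts.

    Defaults follow the study protocol: 1024 hidden units, 5000 epochs,
    batch size 16, learning rate 0.001, at least five restarts.
    """
    X, y = _check_xy(X, y)
    net, curve, log, val_rmse, stats = _fit_restarts(
        lambda rng: MLPRegressorNet(X.shape[1], hidden, rng),
        X, y, X_val, y_val, epochs, batch_size, lr, n_restarts, seed)
    x_mean, x_scale, y_mean, y_scale = stats
    return FittedModel(
        family="BPNN", estimator=net, n_bands=X.shape[1],
        metadata={"hidden": hidden, "epochs": epochs, "batch_size": batch_size,
                  "lr": lr, "n_restarts": n_restarts, "seed": seed,
                  "restarts": log, "val_rmse": val_rmse,
                  "training_curve": curve.tolist()},
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
    )


def fit_cnn(
    X,
    y,
    X_val,
    y_val,
    channels=(16, 32),
    kernels=(7, 5),
    fc_sizes=(256, 64),
    epochs: int = 500,
    batch_size: int = 128,
    lr: float = 1e-3,
    n_restarts: int = 5,
    seed: int = 0,
) -> FittedModel:
    """1-D CNN (two conv + three fc layers), best of seeded restarts.

    Batch size 128 and learning rate 0.001 follow the study protocol; the
    internal layer sizes are configurable. The second convolutional layer is
    addressable by name (``"conv2"``) for saliency analysis.
    """
    X, y = _check_xy(X, y)
    net, curve, log, val_rmse, stats = _fit_restarts(
        lambda rng: ConvNet1D(X.shape[1], rng, channels=channels,
                              kernels=kernels, fc_sizes=fc_sizes),
        X, y, X_val, y_val, epochs, batch_size, lr, n_restarts, seed,
        per_band=False)
    x_mean, x_scale, y_mean, y_scale = stats
    return FittedModel(
        family="CNN", estimator=net, n_bands=X.shape[1],
        metadata={"channels": tuple(channels), "kernels": tuple(kernels),
                  "fc_sizes": tuple(fc_sizes), "epochs": epochs,
                  "batch_size": batch_size, "lr": lr,
                  "n_restarts": n_restarts, "seed": seed, "restarts": log,
                  "val_rmse": val_rmse, "training_curve": curve.tolist()},
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
    )
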