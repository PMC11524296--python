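"""Calibration model families (PLSR, SVR, ANN) behind one fit/predict contract.

Every data-dependent statistic (input/target scaling, hyperparameters) is
learned from calibration data only and frozen into the :class:`FittedModel`;
prediction-time inputs are aligned to the training bands by band identity, so
a permuted column order is fine and an unknown or missing band is a contract
error.

PLSR is latent-variable regression (NIPALS bilinear decomposition) with the
component count fixed or chosen by 10-fold cross-validated RMSE.  SVR is
epsilon-insensitive RBF-kernel regression with a small CV grid search over
(C, gamma, epsilon) on internally standardized inputs.  The ANN is a single
hidden layer of tanh units with a linear output neuron, trained by Adam with
early stopping on an internal validation split; all randomness is seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import (
    BandMismatchError,
    InvalidConfigError,
    TrainingDivergenceError,
)

_FAMILIES = ("plsr", "svr", "ann")

DEFAULT_SVR_GRID = {
    "C": [0.1, 1.0, 10.0, 100.0, 1000.0],
    "gamma": [1e-3, 1e-2, 1e-1, 1.0],
    "epsilon": [0.01, 0.1],
}


@dataclass(frozen=True)
class ModelSpec:
    family: str = "plsr"
    plsr_components: Optional[int] = None       # None = choose by 10-fold RMSECV
    plsr_max_components: int = 20
    svr_kernel: str = "rbf"
    svr_param_grid: Optional[dict] = None       # None = DEFAULT_SVR_GRID
    svr_cv_folds: int = 5
    ann_hidden_units: int = 10
    ann_activation: str = "tanh"
    ann_max_epochs: int = 3000
    ann_patience: int = 200
    target_scaling: str = "standardize"         # "none" | "standardize" (svr/ann only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidConfigError(f"family must be one of {_FAMILIES}")
        if self.ann_hidden_units < 1:
            raise InvalidConfigError("ann_hidden_units must be >= 1")
        if self.target_scaling not in ("none", "standardize"):
            raise InvalidConfigError("target_scaling must be 'none' or 'standardize'")
        if self.svr_param_grid is not None and not self.svr_param_grid:
            raise InvalidConfigError("svr_param_grid must not be empty")


@dataclass
class FittedModel:
    spec: ModelSpec
    bands: list            # band identities (wavelengths or indices), training order
    estimator: object      # opaque learned model
    x_mean: Optional[np.ndarray] = None
    x_sd: Optional[np.ndarray] = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    y_constant: Optional[float] = None  # degenerate constant-target shortcut
    metadata: dict = field(default_factory=dict)

    def predict(self, X_new: np.ndarray, bands: Optional[Sequence] = None) -> np.ndarray:
        return predict(self, X_new, bands)


def _align(model: FittedModel, X_new: np.ndarray, bands: Optional[Sequence]) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2:
        raise InvalidConfigError("X_new must be 2-D")
    if bands is None:
        if X_new.shape[1] != len(model.bands):
            raise BandMismatchError(
                f"expected {len(model.bands)} bands, got {X_new.shape[1]}"
            )
        return X_new
    bands = list(bands)
    if len(bands) != X_new.shape[1]:
        raise BandMismatchError("bands list must label every column of X_new")
    unknown = [b for b in bands if b not in set(model.bands)]
    missing = [b for b in model.bands if b not in set(bands)]
    if unknown or missing:
        raise BandMismatchError(
            f"band set mismatch: unknown columns {unknown}, missing columns {missing}"
        )
    pos = {b: i for i, b in enumerate(bands)}
    return X_new[:, [pos[b] for b in model.bands]]


def predict(model: FittedModel, X_new: np.ndarray, bands: Optional[Sequence] = None) -> np.ndarray:
    """Predict, aligning columns to the training bands by identity."""
    X = _align(model, X_new, bands)
    if model.y_constant is not None:
        return np.full(X.shape[0], model.y_constant)
    if model.x_mean is not None:
        X = (X - model.x_mean) / model.x_sd
    pred = np.asarray(model.estimator.predict(X), dtype=float).ravel()
    pred = pred * model.y_sd + model.y_mean
    if not np.all(np.isfinite(pred)):
        raise TrainingDivergenceError("model produced non-finite predictions")
    return pred


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidConfigError("X must be 2-D with one row per y value")
    if X.shape[0] < 2:
        raise InvalidConfigError("at least 2 samples required")
    return X, y


def _bands_or_default(bands, p: int) -> list:
    return list(range(p)) if bands is None else list(bands)


def _constant_model(spec, bands, y) -> FittedModel:
    return FittedModel(spec, bands, estimator=None, y_constant=float(y[0]),
                       metadata={"degenerate": "constant target"})


def fit_plsr(X, y, spec: ModelSpec = ModelSpec(family="plsr"),
             bands: Optional[Sequence] = None) -> FittedModel:
    """NIPALS partial least squares regression; components fixed or by RMSECV."""
    X, y = _check_xy(X, y)
    bands = _bands_or_default(bands, X.shape[1])
    if np.ptp(y) == 0:
        return _constant_model(spec, bands, y)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    upper = max(1, min(spec.plsr_max_components, rank, X.shape[0] - 1, X.shape[1]))
    if spec.plsr_components is not None:
        if spec.plsr_components > min(rank, X.shape[0] - 1, X.shape[1]):
            raise InvalidConfigError(
                f"plsr_components={spec.plsr_components} exceeds usable rank {rank}"
            )
        ncomp = spec.plsr_components
    else:
        folds = min(10, X.shape[0])
        kf = KFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        best, ncomp = np.inf, 1
        for nc in range(1, upper + 1):
            se = []
            ok = True
            for tr, va in kf.split(X):
                nc_f = min(nc, tr.size - 1)
                m = PLSRegression(n_components=nc_f, scale=False)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        m.fit(X[tr], y[tr])
                    except Exception:
                        ok = False
                        break
                se.append((y[va] - m.predict(X[va]).ravel()) ** 2)
            if not ok:
                continue
            rmse = float(np.sqrt(np.mean(np.concatenate(se))))
            if rmse < best - 1e-12:
                best, ncomp = rmse, nc
    model = PLSRegression(n_components=ncomp, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return FittedModel(spec, bands, model, metadata={"n_components": ncomp})


def fit_svr(X, y, spec: ModelSpec = ModelSpec(family="svr"),
            bands: Optional[Sequence] = None) -> FittedModel:
    """RBF (by default) epsilon-SVR with CV grid search on standardized inputs."""
    X, y = _check_xy(X, y)
    bands = _bands_or_default(bands, X.shape[1])
    if np.ptp(y) == 0:
        return _constant_model(spec, bands, y)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = ((y.mean(), y.std(ddof=0)) if spec.target_scaling == "standardize"
                    else (0.0, 1.0))
    y_sd = y_sd if y_sd > 0 else 1.0
    Xs, ys = (X - x_mean) / x_sd, (y - y_mean) / y_sd
    grid = spec.svr_param_grid if spec.svr_param_grid is not None else DEFAULT_SVR_GRID
    cv = KFold(n_splits=min(spec.svr_cv_folds, X.shape[0]), shuffle=True,
               random_state=spec.seed)
    search = GridSearchCV(SVR(kernel=spec.svr_kernel), grid, cv=cv,
                          scoring="neg_root_mean_squared_error", n_jobs=None)
    search.fit(Xs, ys)
    return FittedModel(spec, bands, search.best_estimator_, x_mean=x_mean, x_sd=x_sd,
                       y_mean=float(y_mean), y_sd=float(y_sd),
                       metadata={"best_params": search.best_params_})


def fit_ann(X, y, spec: ModelSpec = ModelSpec(family="ann"),
            bands: Optional[Sequence] = None) -> FittedModel:
    """Single-hidden-layer feed-forward network, seeded, with early stopping."""
    X, y = _check_xy(X, y)
    bands = _bands_or_default(bands, X.shape[1])
    if np.ptp(y) == 0:
        return _constant_model(spec, bands, y)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = ((y.mean(), y.std(ddof=0)) if spec.target_scaling == "standardize"
                    else (0.0, 1.0))
    y_sd = y_sd if y_sd > 0 else 1.0
    Xs, ys = (X - x_mean) / x_sd, (y - y_mean) / y_sd
    net = MLPRegressor(
        hidden_layer_sizes=(spec.ann_hidden_units,),
        activation=spec.ann_activation,
        solver="adam",
        learning_rate_init=0.01,
        max_iter=spec.ann_max_epochs,
        early_stopping=True,
        validation_fraction=0.15,
        n_iter_no_change=spec.ann_patience,
        tol=1e-7,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(Xs, ys)
    params_finite = all(np.all(np.isfinite(w)) for w in net.coefs_ + net.intercepts_)
    if not params_finite or not np.isfinite(net.loss_):
        raise TrainingDivergenceError(
            f"ANN training diverged (loss={net.loss_!r}); try a smaller learning rate"
        )
    return FittedModel(spec, bands, net, x_mean=x_mean, x_sd=x_sd,
                       y_mean=float(y_mean), y_sd=float(y_sd),
                       metadata={"n_iter": net.n_iter_, "loss": float(net.loss_)})


def fit_model(X, y, spec: ModelSpec, bands: Optional[Sequence] = None) -> FittedModel:
    """Dispatch on ``spec.family``."""
    fitter = {"plsr": fit_plsr, "svr": fit_svr, "ann": fit_ann}[spec.family]
    return fitter(X, y, spec, bands)
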