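"""Calibration/prediction splitting, the R^2 / RMSE metrics, and the full grid run.

The dataset is split 70/30 stratified by drought group (126/54 seedlings at
the default n = 180), all fitting — preprocessing state, band selection,
hyperparameters — is confined to the calibration split, and every
(preprocessing x selector x model x trait) combination contributes one row to
a comparison report with calibration- and prediction-set R^2 and RMSE:

    R^2  = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2
    RMSE = sqrt( sum_i (y_i - yhat_i)^2 / n )

LWC is carried as a fraction internally; render as percent at the formatting
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, StratificationError, UndefinedMetricError
from .models import ModelSpec, fit_model
from .preprocess import Preprocessor, PreprocessSpec
from .selection import (
    CarsConfig,
    SelectionResult,
    SpaConfig,
    cars_select,
    full_selection,
    spa_select,
)
from .spectra import SpectraSet


# ------------------------------------------------------------------ metrics
def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise InvalidConfigError("r_squared needs two equal-length vectors, n >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("R^2 undefined for a constant reference vector")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size == 0:
        raise InvalidConfigError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


# -------------------------------------------------------------------- split
@dataclass(frozen=True)
class SplitPlan:
    calibration_ids: tuple
    prediction_ids: tuple
    calibration_fraction: float
    seed: int

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_prediction(self) -> int:
        return len(self.prediction_ids)


def split_calibration_prediction(
    spectra: SpectraSet,
    calibration_fraction: float = 0.7,
    seed: int = 0,
) -> SplitPlan:
    """Seeded stratified (by drought group) split.

    Per-group calibration counts are allocated by the largest-remainder rule so
    every group's proportion is within one sample of the global fraction; at
    n = 180 with five groups of 36 the default fraction gives exactly 126/54.
    """
    if not (0.0 <= calibration_fraction <= 1.0):
        raise InvalidConfigError("calibration_fraction must be in [0, 1]")
    groups = spectra.groups
    ids = np.asarray(spectra.ids)
    rng = np.random.default_rng(seed)
    uniq = list(dict.fromkeys(groups))  # preserve first-appearance order
    sizes = {g: int((groups == g).sum()) for g in uniq}
    for g, sz in sizes.items():
        if sz < 2:
            raise StratificationError(f"group {g!r} has {sz} sample(s); cannot stratify")
    n_total = len(ids)
    target_total = int(round(calibration_fraction * n_total))
    raw = {g: calibration_fraction * sizes[g] for g in uniq}
    alloc = {g: int(np.floor(raw[g])) for g in uniq}
    remainder = target_total - sum(alloc.values())
    by_frac = sorted(uniq, key=lambda g: (-(raw[g] - alloc[g]), uniq.index(g)))
    for g in by_frac[:remainder]:
        alloc[g] += 1
    cal, pred = [], []
    for g in uniq:
        members = ids[groups == g]
        perm = rng.permutation(len(members))
        cal.extend(members[perm[: alloc[g]]])
        pred.extend(members[perm[alloc[g]:]])
    return SplitPlan(tuple(cal), tuple(pred), calibration_fraction, seed)


# ----------------------------------------------------------------- pipeline
@dataclass
class PipelineConfig:
    """One grid run: which preprocessings, selectors, models and traits to cross."""

    targets: Sequence[str] = ("lcc", "lwc")
    preprocess_methods: Sequence[str] = ("sg",)
    selectors: Sequence[str] = ("full", "spa", "cars")
    models: Sequence[str] = ("plsr", "svr", "ann")
    calibration_fraction: float = 0.7
    seed: int = 0
    preprocess_spec: PreprocessSpec = field(default_factory=PreprocessSpec)
    spa_config: SpaConfig = field(default_factory=SpaConfig)
    cars_config: CarsConfig = field(default_factory=CarsConfig)
    model_specs: Optional[dict] = None  # family -> ModelSpec overrides


@dataclass
class EvaluationReport:
    """Comparison table: one row per grid cell, plus provenance metadata."""

    table: pd.DataFrame
    split: SplitPlan
    selections: dict  # (preprocess, selector, target) -> SelectionResult
    metadata: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _select_bands(method, X_cal, y_cal, grid, cfg: PipelineConfig) -> SelectionResult:
    if method == "full":
        return full_selection(grid)
    if method == "spa":
        sc = cfg.spa_config
        return spa_select(X_cal, y_cal, SpaConfig(sc.k_min, sc.k_max,
                                                  sc.holdout_fraction, cfg.seed),
                          grid=grid)
    if method == "cars":
        cc = cfg.cars_config
        return cars_select(X_cal, y_cal,
                           CarsConfig(cc.n_runs, cc.cv_folds, cc.mc_fraction,
                                      cc.max_pls_components, cc.pls_components,
                                      cfg.seed),
                           grid=grid)
    raise InvalidConfigError(f"unknown selector {method!r}")


def run_pipeline(spectra: SpectraSet, config: PipelineConfig = PipelineConfig()) -> EvaluationReport:
    """Run the preprocessing x selection x model grid on one dataset.

    All fitting is confined to the calibration split.  A failure in one grid
    cell marks that row ``failed`` with the reason and the run continues.
    """
    plan = split_calibration_prediction(spectra, config.calibration_fraction, config.seed)
    if plan.n_prediction == 0:
        raise InvalidConfigError("prediction set is empty; nothing to evaluate")
    cal_raw = spectra.subset(plan.calibration_ids)
    pred_raw = spectra.subset(plan.prediction_ids)

    rows = []
    selections: dict = {}
    for prep_name in config.preprocess_methods:
        spec = PreprocessSpec(
            method=prep_name,
            sg_window=config.preprocess_spec.sg_window,
            sg_polyorder=config.preprocess_spec.sg_polyorder,
            sg_deriv=config.preprocess_spec.sg_deriv,
        )
        prep = Preprocessor(spec)
        cal = prep.fit_transform(cal_raw)
        pred = prep.transform(pred_raw)
        for target in config.targets:
            y_cal, y_pred = cal.target(target), pred.target(target)
            for sel_name in config.selectors:
                key = (prep_name, sel_name, target)
                try:
                    if key not in selections:
                        selections[key] = _select_bands(
                            sel_name, cal.matrix, y_cal, spectra.grid, config
                        )
                    sel = selections[key]
                except Exception as exc:
                    for model_name in config.models:
                        rows.append(_failed_row(target, prep_name, sel_name,
                                                model_name, f"selection failed: {exc}"))
                    continue
                bands = [float(w) for w in sel.selected_wavelengths_nm]
                Xc = cal.matrix[:, sel.selected_indices]
                Xp = pred.matrix[:, sel.selected_indices]
                for model_name in config.models:
                    mspec = (config.model_specs or {}).get(
                        model_name, ModelSpec(family=model_name, seed=config.seed)
                    )
                    try:
                        fitted = fit_model(Xc, y_cal, mspec, bands=bands)
                        yc_hat = fitted.predict(Xc, bands=bands)
                        yp_hat = fitted.predict(Xp, bands=bands)
                        rows.append({
                            "index": target.upper(),
                            "preprocessing": prep_name,
                            "selector": sel_name,
                            "n_bands": sel.n_selected,
                            "model": model_name,
                            "r2_c": r_squared(y_cal, yc_hat),
                            "rmse_c": rmse(y_cal, yc_hat),
                            "r2_p": r_squared(y_pred, yp_hat),
                            "rmse_p": rmse(y_pred, yp_hat),
                            "status": "ok",
                            "reason": "",
                        })
                    except Exception as exc:
                        warnings.warn(f"grid cell {key}+{model_name} failed: {exc}",
                                      RuntimeWarning)
                        rows.append(_failed_row(target, prep_name, sel_name,
                                                model_name, str(exc)))
    table = pd.DataFrame(rows)
    meta = {
        "seed": config.seed,
        "n_calibration": plan.n_calibration,
        "n_prediction": plan.n_prediction,
    }
    return EvaluationReport(table, plan, selections, meta)


def _failed_row(target, prep, sel, model, reason) -> dict:
    return {
        "index": target.upper(), "preprocessing": prep, "selector": sel,
        "n_bands": np.nan, "model": model,
        "r2_c": np.nan, "rmse_c": np.nan, "r2_p": np.nan, "rmse_p": np.nan,
        "status": "failed", "reason": reason,
    }
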