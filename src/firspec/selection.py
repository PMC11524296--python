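"""Characteristic-wavelength selection: SPA and CARS.

SPA (successive projections algorithm) builds, from each candidate start
band, a chain of minimally collinear bands: at every step the remaining band
columns are projected onto the orthogonal complement of the span of the
already-selected columns and the one with the largest residual norm joins the
chain.  Multiple linear regression on each chain prefix is scored on a
held-out validation split and the (size, chain) with the lowest RMSE wins.

CARS (competitive adaptive reweighted sampling) runs N Monte-Carlo rounds.
In round i a random subset of calibration samples is drawn, a PLS model is
fitted on the surviving bands, and bands compete on |regression coefficient|:
the number of survivors follows the exponentially decreasing function (EDF)

    r_i = a * exp(-k * i),   a = (p/2)^(1/(N-1)),   k = ln(p/2)/(N-1)

(all p bands at round 1, exactly 2 at round N), and which bands survive is
decided by adaptive reweighted sampling, here weighted sampling without
replacement with weights proportional to |coefficient|.  Drawing without
replacement keeps the retained-count sequence exactly on the EDF schedule
while preserving the competitive, stochastic character of the resampling
(the more common draw-with-replacement-then-deduplicate variant undershoots
the schedule).  Every round's band set is scored by k-fold cross-validated
RMSE on the full calibration set and the round with the lowest RMSECV wins.

Ties anywhere are broken toward the smaller subset, then the lexicographically
smallest band-index list, for reproducibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .errors import InvalidConfigError
from .grid import WavelengthGrid

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class SpaConfig:
    k_min: int = 1
    k_max: int = 30
    holdout_fraction: float = 0.2  # validation share of the calibration set; 0 = score in-sample
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise InvalidConfigError("need 1 <= k_min <= k_max")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise InvalidConfigError("holdout_fraction must be in [0, 1)")


@dataclass(frozen=True)
class CarsConfig:
    n_runs: int = 50
    cv_folds: int = 10
    mc_fraction: float = 0.8
    max_pls_components: int = 10
    pls_components: Optional[int] = None  # fixed count; None = inner-CV choice per run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise InvalidConfigError("n_runs must be >= 2")
        if not (0.0 < self.mc_fraction < 1.0):
            raise InvalidConfigError("mc_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise InvalidConfigError("cv_folds must be >= 2")
        if self.max_pls_components < 1:
            raise InvalidConfigError("max_pls_components must be >= 1")


@dataclass
class SelectionResult:
    """Selected bands plus the diagnostic trajectory that justified them."""

    method: str
    selected_indices: np.ndarray            # ordered band indices into the grid
    selected_wavelengths_nm: np.ndarray
    rmse_trajectory: np.ndarray             # per subset size (SPA) / per run (CARS)
    chosen_point: int                       # index into the trajectory
    retained_counts: Optional[np.ndarray] = None  # CARS only: survivors per run

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)


# ----------------------------------------------------------------------- SPA
def spa_project_chain(X: np.ndarray, start_band: int, k: int) -> np.ndarray:
    """Greedy orthogonal-projection chain of length <= k starting at ``start_band``.

    Equivalent to a Gram-Schmidt pivoting order.  If the residual matrix
    becomes numerically rank deficient before k bands are collected, the chain
    is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (0 <= start_band < p):
        raise InvalidConfigError("start_band outside the band range")
    if k > min(n, p):
        raise InvalidConfigError("chain length k cannot exceed min(n_samples, n_bands)")
    P = X.copy()
    scale = max(float(np.linalg.norm(X, axis=0).max()), 1.0)
    chain = [start_band]
    selected = np.zeros(p, dtype=bool)
    selected[start_band] = True
    for _ in range(k - 1):
        x = P[:, chain[-1]]
        nx = float(x @ x)
        if nx <= (_RANK_TOL * scale) ** 2:
            break
        P = P - np.outer(x, x @ P) / nx
        norms = np.linalg.norm(P, axis=0)
        norms[selected] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= _RANK_TOL * scale:
            warnings.warn(
                f"SPA chain truncated at {len(chain)} bands: residuals rank deficient",
                RuntimeWarning,
            )
            break
        chain.append(j)
        selected[j] = True
    return np.asarray(chain, dtype=int)


def _mlr_rmse(X_tr, y_tr, X_va, y_va, cols: np.ndarray) -> float:
    A = np.column_stack([X_tr[:, cols], np.ones(X_tr.shape[0])])
    coef, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
    pred = np.column_stack([X_va[:, cols], np.ones(X_va.shape[0])]) @ coef
    return float(np.sqrt(np.mean((y_va - pred) ** 2)))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SpaConfig = SpaConfig(),
    grid: Optional[WavelengthGrid] = None,
    candidate_starts: Optional[Sequence[int]] = None,
) -> SelectionResult:
    """SPA band selection scored by holdout multiple-linear-regression RMSE.

    For every candidate start band a chain of length ``k_max`` is grown once
    (prefixes give the chains for every smaller k).  The trajectory records
    the best RMSE at each subset size; the winner is the global minimum under
    the smaller-subset-first tie rule.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise InvalidConfigError("X row count must equal y length")
    rng = np.random.default_rng(config.seed)
    if config.holdout_fraction > 0:
        n_val = max(1, int(round(config.holdout_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        tr_idx = val_idx = np.arange(n)
    X_tr, y_tr, X_va, y_va = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    if config.k_max >= X_tr.shape[0]:
        raise InvalidConfigError(
            f"k_max={config.k_max} leaves MLR underdetermined with "
            f"{X_tr.shape[0]} training samples"
        )
    k_max = min(config.k_max, p)
    if config.k_min > k_max:
        raise InvalidConfigError("k_min exceeds usable band count")

    starts = range(p) if candidate_starts is None else candidate_starts
    ks = np.arange(config.k_min, k_max + 1)
    best_per_k = np.full(ks.size, np.inf)
    best_chain_per_k: list[Optional[np.ndarray]] = [None] * ks.size
    for s in starts:
        chain = spa_project_chain(X_tr, int(s), k_max)
        for ki, k in enumerate(ks):
            if k > chain.size:
                break
            rmse = _mlr_rmse(X_tr, y_tr, X_va, y_va, chain[:k])
            better = rmse < best_per_k[ki] - 1e-15
            tie = (
                abs(rmse - best_per_k[ki]) <= 1e-15
                and best_chain_per_k[ki] is not None
                and list(chain[:k]) < list(best_chain_per_k[ki])
            )
            if better or tie:
                best_per_k[ki] = rmse
                best_chain_per_k[ki] = chain[:k].copy()

    finite = np.isfinite(best_per_k)
    if not finite.any():
        raise InvalidConfigError("SPA found no scorable subset")
    chosen = int(np.flatnonzero(finite)[np.argmin(best_per_k[finite])])
    chain = best_chain_per_k[chosen]
    wl = (grid.wavelengths_nm[chain] if grid is not None else np.asarray(chain, dtype=float))
    return SelectionResult(
        method="spa",
        selected_indices=np.asarray(chain, dtype=int),
        selected_wavelengths_nm=wl,
        rmse_trajectory=best_per_k,
        chosen_point=chosen,
    )


# ---------------------------------------------------------------------- CARS
def cars_edf_ratio(run_index: int, n_bands: int, n_runs: int) -> float:
    """EDF retention ratio r_i with r_1*p = p and r_N*p = 2."""
    if n_bands < 2:
        raise InvalidConfigError("EDF needs at least 2 bands")
    if not (1 <= run_index <= n_runs):
        raise InvalidConfigError("run_index must lie in [1, n_runs]")
    a = (n_bands / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(n_bands / 2.0) / (n_runs - 1)
    return a * math.exp(-k * run_index)


def cars_retained_count(run_index: int, n_bands: int, n_runs: int) -> int:
    """ceil(r_i * p), with a guard so float error cannot push the boundaries off."""
    r = cars_edf_ratio(run_index, n_bands, n_runs)
    return max(2, min(n_bands, int(math.ceil(r * n_bands - 1e-9))))


def _pls_coef(X: np.ndarray, y: np.ndarray, ncomp: int) -> np.ndarray:
    model = PLSRegression(n_components=ncomp, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return np.abs(model.coef_).ravel()


def _cv_rmse_pls(X: np.ndarray, y: np.ndarray, ncomp: int, folds: int, seed: int) -> float:
    kf = KFold(n_splits=min(folds, X.shape[0]), shuffle=True, random_state=seed)
    errs = []
    for tr, va in kf.split(X):
        nc = max(1, min(ncomp, X.shape[1], tr.size - 1))
        model = PLSRegression(n_components=nc, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[tr], y[tr])
        errs.append((y[va] - model.predict(X[va]).ravel()) ** 2)
    return float(np.sqrt(np.mean(np.concatenate(errs))))


def _choose_ncomp(X: np.ndarray, y: np.ndarray, max_comp: int, seed: int) -> int:
    """Small inner CV over the component count (5 folds)."""
    upper = max(1, min(max_comp, X.shape[1], X.shape[0] - 2))
    if upper == 1:
        return 1
    scores = [_cv_rmse_pls(X, y, nc, 5, seed) for nc in range(1, upper + 1)]
    return int(np.argmin(scores)) + 1


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    config: CarsConfig = CarsConfig(),
    grid: Optional[WavelengthGrid] = None,
) -> SelectionResult:
    """CARS band selection: MC sampling, EDF schedule, ARS competition, CV scoring."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise InvalidConfigError("X row count must equal y length")
    if p < 2:
        raise InvalidConfigError("CARS needs at least 2 bands")
    if config.cv_folds > n:
        raise InvalidConfigError("cv_folds cannot exceed the sample count")
    rng = np.random.default_rng(config.seed)
    score_seed = int(rng.integers(0, 2**31 - 1))

    pool = np.arange(p)
    counts = np.empty(config.n_runs, dtype=int)
    rmsecv = np.full(config.n_runs, np.inf)
    sets: list[np.ndarray] = []
    n_sub = max(2, int(round(config.mc_fraction * n)))

    for i in range(1, config.n_runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        Xs, ys = X[np.ix_(rows, pool)], y[rows]
        try:
            if config.pls_components is not None:
                ncomp = max(1, min(config.pls_components, pool.size, n_sub - 1))
            else:
                ncomp = _choose_ncomp(Xs, ys, config.max_pls_components, score_seed)
            w = _pls_coef(Xs, ys, ncomp)
        except Exception as exc:  # degenerate subsample: skip, never silently score
            warnings.warn(f"CARS run {i} skipped: PLS failed ({exc})", RuntimeWarning)
            counts[i - 1] = pool.size
            sets.append(pool.copy())
            continue
        n_keep = min(pool.size, cars_retained_count(i, p, config.n_runs))
        if n_keep < pool.size:
            total = w.sum()
            if total > 0:
                probs = w / total
                nonzero = int(np.count_nonzero(probs))
                if nonzero >= n_keep:
                    keep_local = rng.choice(pool.size, size=n_keep, replace=False, p=probs)
                else:  # too few competitive bands: keep all of them, fill uniformly
                    nz = np.flatnonzero(probs)
                    rest = np.setdiff1d(np.arange(pool.size), nz)
                    fill = rng.choice(rest, size=n_keep - nonzero, replace=False)
                    keep_local = np.concatenate([nz, fill])
            else:
                keep_local = rng.choice(pool.size, size=n_keep, replace=False)
            pool = np.sort(pool[keep_local])
        counts[i - 1] = pool.size
        sets.append(pool.copy())
        try:
            nc_score = max(1, min(ncomp, pool.size))
            rmsecv[i - 1] = _cv_rmse_pls(X[:, pool], y, nc_score, config.cv_folds, score_seed)
        except Exception as exc:
            warnings.warn(f"CARS run {i} unscored: CV failed ({exc})", RuntimeWarning)

    if not np.isfinite(rmsecv).any():
        raise InvalidConfigError("no CARS run could be scored")
    # minimal RMSECV; ties -> smaller subset, then lexicographically smaller set
    order = sorted(
        range(config.n_runs),
        key=lambda j: (rmsecv[j], sets[j].size, tuple(sets[j])),
    )
    best = order[0]
    chosen_set = sets[best]
    wl = (grid.wavelengths_nm[chosen_set] if grid is not None
          else np.asarray(chosen_set, dtype=float))
    return SelectionResult(
        method="cars",
        selected_indices=chosen_set,
        selected_wavelengths_nm=wl,
        rmse_trajectory=rmsecv,
        chosen_point=best,
        retained_counts=counts,
    )


def full_selection(grid: WavelengthGrid) -> SelectionResult:
    """Identity selection: every band on the grid."""
    idx = np.arange(grid.n_bands)
    return SelectionResult(
        method="full",
        selected_indices=idx,
        selected_wavelengths_nm=grid.wavelengths_nm.copy(),
        rmse_trajectory=np.array([]),
        chosen_point=0,
    )
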