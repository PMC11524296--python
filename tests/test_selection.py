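"""SPA projection chains and CARS competitive elimination."""

import warnings

import numpy as np
import pytest

import firspec as fs
from firspec.errors import InvalidConfigError
from firspec.selection import cars_retained_count


def brute_force_chain(X, start, k):
    """Independent oracle: explicit orthogonal-complement projectors at every step."""
    n, p = X.shape
    chain = [start]
    for _ in range(k - 1):
        S = X[:, chain]
        P_perp = np.eye(n) - S @ np.linalg.pinv(S)
        residual_norms = np.linalg.norm(P_perp @ X, axis=0)
        residual_norms[chain] = -1.0
        chain.append(int(np.argmax(residual_norms)))
    return np.array(chain)


# ----------------------------------------------------------------------- SPA
def test_spa_orders_orthogonal_columns_by_norm():
    X = np.diag([3.0, 7.0, 1.0, 5.0])
    chain = fs.spa_project_chain(X, start_band=1, k=4)
    np.testing.assert_array_equal(chain, [1, 3, 0, 2])


def test_spa_chain_matches_projection_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = int(rng.integers(5, 9))
        X = rng.normal(size=(8, p))
        start = int(rng.integers(p))
        k = int(rng.integers(2, p + 1))
        np.testing.assert_array_equal(
            fs.spa_project_chain(X, start, k), brute_force_chain(X, start, k)
        )


def test_spa_never_selects_a_duplicate_after_its_twin():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 6))
    X[:, 4] = X[:, 2]  # exact collinearity
    with pytest.warns(RuntimeWarning, match="truncated"):
        chain = fs.spa_project_chain(X, start_band=2, k=6)
    assert not (2 in chain and 4 in chain)


def noiseless_spectral_instance(seed=2, n_bands=30, planted=(4, 12, 25)):
    """Noiseless synthetic spectra are exactly rank 3 (baseline + two trait
    directions), so a target linear in 3 bands is recoverable from any
    independent 3-band subset — the setting in which SPA must reach RMSE ~ 0
    by k = 3."""
    cfg = fs.SyntheticConfig(
        seed=seed, n_per_group=8, noise_sd=0.0, scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        grid=fs.WavelengthGrid(np.linspace(870.0, 1720.0, n_bands)),
    )
    X = fs.simulate_dataset(cfg).matrix
    y = X[:, list(planted)] @ [2.0, -1.5, 1.0]
    return X, y


def test_spa_select_recovers_planted_linear_signal():
    X, y = noiseless_spectral_instance()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # rank-3 X truncates chains
        res = fs.spa_select(X, y, fs.SpaConfig(k_min=1, k_max=6, seed=0))
    traj = res.rmse_trajectory
    finite = traj[np.isfinite(traj)]
    assert np.all(np.diff(finite) <= 1e-12)  # non-increasing
    assert traj[2] < 1e-8  # exact by k = 3
    assert res.rmse_trajectory[res.chosen_point] < 1e-8
    assert res.n_selected <= 3


def test_spa_single_band_equals_exhaustive_search():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 12))
    y = 1.3 * X[:, 7] + rng.normal(0, 0.05, 30)
    cfg = fs.SpaConfig(k_min=1, k_max=1, holdout_fraction=0.0, seed=0)
    res = fs.spa_select(X, y, cfg)

    def univariate_rmse(j):
        A = np.column_stack([X[:, j], np.ones(30)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return np.sqrt(np.mean((y - A @ coef) ** 2))

    best = min(range(12), key=univariate_rmse)
    assert res.selected_indices.tolist() == [best]


def test_spa_underdetermined_config_rejected():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 40))
    y = rng.normal(size=20)
    with pytest.raises(InvalidConfigError):
        fs.spa_select(X, y, fs.SpaConfig(k_min=1, k_max=25, seed=0))


def test_spa_deterministic_under_fixed_seed():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 20))
    y = rng.normal(size=30)
    a = fs.spa_select(X, y, fs.SpaConfig(k_max=5, seed=9))
    b = fs.spa_select(X, y, fs.SpaConfig(k_max=5, seed=9))
    np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
    np.testing.assert_array_equal(a.rmse_trajectory, b.rmse_trajectory)


# ----------------------------------------------------------------------- EDF
def test_edf_boundary_conditions():
    for p in (50, 512):
        assert cars_retained_count(1, p, 50) == p
        assert cars_retained_count(50, p, 50) == 2


def test_edf_closed_form_matches_independent_evaluation():
    p, N, i = 512, 50, 25
    a = (p / 2) ** (1 / (N - 1))
    k = np.log(p / 2) / (N - 1)
    assert fs.cars_edf_ratio(i, p, N) == pytest.approx(a * np.exp(-k * i), rel=1e-12)


def test_edf_invalid_inputs():
    with pytest.raises(InvalidConfigError):
        fs.cars_edf_ratio(1, 1, 50)
    with pytest.raises(InvalidConfigError):
        fs.cars_edf_ratio(0, 512, 50)
    with pytest.raises(InvalidConfigError):
        fs.cars_edf_ratio(51, 512, 50)


# ---------------------------------------------------------------------- CARS
@pytest.fixture(scope="module")
def cars_instance():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(60, 50))
    y = X[:, [4, 22, 37]] @ [2.0, -1.5, 1.0]
    return X, y


def test_cars_counts_follow_edf_and_decrease(cars_instance):
    X, y = cars_instance
    res = fs.cars_select(X, y, fs.CarsConfig(n_runs=50, seed=0, pls_components=5))
    counts = res.retained_counts
    assert np.all(np.diff(counts) <= 0)
    expected = [cars_retained_count(i, 50, 50) for i in range(1, 51)]
    assert np.all(np.abs(counts - expected) <= 1)


def test_cars_chosen_run_minimises_rmsecv(cars_instance):
    X, y = cars_instance
    res = fs.cars_select(X, y, fs.CarsConfig(n_runs=50, seed=0, pls_components=5))
    finite = np.isfinite(res.rmse_trajectory)
    assert res.rmse_trajectory[res.chosen_point] == pytest.approx(
        res.rmse_trajectory[finite].min()
    )


def test_cars_keeps_planted_bands(cars_instance):
    X, y = cars_instance
    for seed in range(3):
        res = fs.cars_select(X, y, fs.CarsConfig(n_runs=50, seed=seed, pls_components=5))
        assert {4, 22, 37} <= set(res.selected_indices.tolist())


def test_cars_deterministic_under_fixed_seed(cars_instance):
    X, y = cars_instance
    a = fs.cars_select(X, y, fs.CarsConfig(n_runs=30, seed=3, pls_components=5))
    b = fs.cars_select(X, y, fs.CarsConfig(n_runs=30, seed=3, pls_components=5))
    np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
    np.testing.assert_array_equal(a.rmse_trajectory, b.rmse_trajectory)


def test_selected_indices_map_to_grid_wavelengths(small_dataset):
    y = small_dataset.target("lwc")
    res = fs.cars_select(small_dataset.matrix, y,
                         fs.CarsConfig(n_runs=20, seed=0, pls_components=3),
                         grid=small_dataset.grid)
    np.testing.assert_array_equal(
        res.selected_wavelengths_nm,
        small_dataset.grid.wavelengths_nm[res.selected_indices],
    )
    assert len(set(res.selected_indices.tolist())) == res.n_selected


def test_cars_invalid_configs():
    with pytest.raises(InvalidConfigError):
        fs.CarsConfig(n_runs=1)
    with pytest.raises(InvalidConfigError):
        fs.CarsConfig(mc_fraction=1.0)
    rng = np.random.default_rng(0)
    with pytest.raises(InvalidConfigError):
        fs.cars_select(rng.normal(size=(5, 10)), rng.normal(size=5),
                       fs.CarsConfig(cv_folds=10))
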