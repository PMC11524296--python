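"""ENVI round-trips, white/dark calibration, canopy masking and ROI extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import firspec as fs
from firspec.cube_io import Hypercube, Mask, ReferenceFrames
from firspec.errors import (
    EmptyROIError,
    EnviSizeMismatchError,
    MissingWavelengthError,
    ReferenceDegeneracyError,
    UnknownInterleaveError,
)
from firspec.synthetic import clean_spectrum


@pytest.fixture
def tiny_grid():
    return fs.WavelengthGrid(np.linspace(870.0, 900.0, 6))


@pytest.mark.parametrize("interleave", ["bsq", "bil"])
def test_envi_round_trip_is_lossless(tmp_path, tiny_grid, interleave):
    rng = np.random.default_rng(0)
    cube = Hypercube(rng.random((4, 5, 6)), tiny_grid, interleave=interleave)
    header = fs.write_envi(cube, tmp_path / "cube.hdr")
    back = fs.read_envi(header)
    np.testing.assert_array_equal(back.data, cube.data)
    assert back.grid == tiny_grid
    assert back.interleave == interleave


def test_header_wavelength_count_mismatch_is_an_error(tmp_path, tiny_grid):
    cube = Hypercube(np.zeros((2, 3, 6)), tiny_grid)
    header = fs.write_envi(cube, tmp_path / "cube.hdr")
    text = header.read_text().replace(", 900.0000 }", " }")
    header.write_text(text)
    with pytest.raises(MissingWavelengthError):
        fs.read_envi(header)


def test_unknown_interleave_is_an_error(tmp_path, tiny_grid):
    cube = Hypercube(np.zeros((2, 3, 6)), tiny_grid)
    header = fs.write_envi(cube, tmp_path / "cube.hdr")
    header.write_text(header.read_text().replace("interleave = bsq", "interleave = bip"))
    with pytest.raises(UnknownInterleaveError):
        fs.read_envi(header)


def test_binary_size_mismatch_is_an_error(tmp_path, tiny_grid):
    cube = Hypercube(np.zeros((2, 3, 6)), tiny_grid)
    header = fs.write_envi(cube, tmp_path / "cube.hdr")
    data = header.with_suffix(".img")
    data.write_bytes(data.read_bytes()[:-8])
    with pytest.raises(EnviSizeMismatchError):
        fs.read_envi(header)


def _refs(shape, white=100.0, dark=10.0):
    return ReferenceFrames(np.full(shape, white), np.full(shape, dark))


@pytest.mark.parametrize(
    "raw_value, expected",
    [(100.0, 1.0), (10.0, 0.0), (55.0, 0.5)],  # I=W, I=D, I=(W+D)/2
)
def test_calibration_endpoints_and_midpoint(tiny_grid, raw_value, expected):
    shape = (3, 4, 6)
    raw = Hypercube(np.full(shape, raw_value), tiny_grid)
    refl = fs.calibrate_reflectance(raw, _refs(shape))
    np.testing.assert_allclose(refl.data, expected)
    assert refl.is_reflectance


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_calibration_invariant_under_common_scaling(scale):
    grid = fs.WavelengthGrid(np.linspace(870.0, 900.0, 4))
    rng = np.random.default_rng(1)
    shape = (2, 3, 4)
    I = 10 + 80 * rng.random(shape)
    W, D = np.full(shape, 100.0), np.full(shape, 10.0)
    r1 = fs.calibrate_reflectance(Hypercube(I, grid), ReferenceFrames(W, D))
    r2 = fs.calibrate_reflectance(Hypercube(I * scale, grid),
                                  ReferenceFrames(W * scale, D * scale))
    np.testing.assert_allclose(r1.data, r2.data, rtol=1e-9)


def test_white_equals_dark_raises_with_location(tiny_grid):
    shape = (2, 2, 6)
    white = np.full(shape, 100.0)
    white[1, 0, 3] = 10.0  # degenerate pixel/band
    refs = ReferenceFrames(white, np.full(shape, 10.0))
    with pytest.raises(ReferenceDegeneracyError, match=r"\(1, 0, 3\)"):
        fs.calibrate_reflectance(Hypercube(np.zeros(shape), tiny_grid), refs)


def test_scanline_references_broadcast_along_lines(tiny_grid):
    shape = (5, 3, 6)
    raw = Hypercube(np.full(shape, 55.0), tiny_grid)
    refs = ReferenceFrames(np.full(shape[1:], 100.0), np.full(shape[1:], 10.0))
    refl = fs.calibrate_reflectance(raw, refs)
    np.testing.assert_allclose(refl.data, 0.5)


@pytest.mark.parametrize("value, included", [(0.5, True), (0.45, True), (0.449, False)])
def test_mask_threshold_is_inclusive(tiny_grid, value, included):
    cube = Hypercube(np.full((2, 2, 6), value), tiny_grid, is_reflectance=True)
    mask = fs.make_mask(cube, threshold=0.45)
    assert mask.values.all() == included


def test_all_zero_cube_gives_flagged_empty_mask(tiny_grid):
    cube = Hypercube(np.zeros((3, 3, 6)), tiny_grid, is_reflectance=True)
    mask = fs.make_mask(cube)
    assert mask.is_empty
    with pytest.raises(EmptyROIError):
        fs.extract_roi_mean(cube, mask)


def test_roi_mean_of_two_pixels(tiny_grid):
    data = np.zeros((1, 2, 6))
    data[0, 0] = 0.2
    data[0, 1] = 0.4
    cube = Hypercube(data, tiny_grid, is_reflectance=True)
    mask = Mask(np.ones((1, 2), dtype=bool), 0.0, "manual")
    spectrum = fs.extract_roi_mean(cube, mask)
    np.testing.assert_allclose(spectrum.values, 0.3)
    assert spectrum.n_pixels == 2


def test_roi_mean_bounded_and_permutation_invariant(tiny_grid):
    rng = np.random.default_rng(2)
    data = rng.random((4, 4, 6))
    cube = Hypercube(data, tiny_grid, is_reflectance=True)
    mask = Mask(rng.random((4, 4)) > 0.3, 0.0, "manual")
    spectrum = fs.extract_roi_mean(cube, mask)
    pixels = data[mask.values]
    assert np.all(spectrum.values >= pixels.min(axis=0) - 1e-12)
    assert np.all(spectrum.values <= pixels.max(axis=0) + 1e-12)
    shuffled = pixels[rng.permutation(pixels.shape[0])]
    np.testing.assert_allclose(spectrum.values, shuffled.mean(axis=0), atol=1e-12)


# ------------------------------------------------- synthetic cube fixtures
def test_simulated_cube_mask_recovery_and_grid():
    cfg = fs.SyntheticConfig(seed=3)
    truth = fs.simulate_traits(cfg)[0]
    cube, refs, true_mask = fs.simulate_cube(truth, cfg)
    refl = fs.calibrate_reflectance(cube, refs)
    mask = fs.make_mask(refl, threshold=0.45)
    np.testing.assert_array_equal(mask.values, true_mask.values)
    assert refl.grid == cfg.grid


def test_simulated_cube_envi_round_trip_preserves_default_grid(tmp_path):
    cfg = fs.SyntheticConfig(seed=3, grid=fs.WavelengthGrid(np.linspace(870, 1720, 32)))
    truth = fs.simulate_traits(cfg)[0]
    cube, _, _ = fs.simulate_cube(truth, cfg, scene_shape=(6, 6))
    back = fs.read_envi(fs.write_envi(cube, tmp_path / "scene.hdr"))
    assert back.grid == cfg.grid


def test_zero_noise_roi_mean_equals_injected_spectrum():
    cfg = fs.SyntheticConfig(seed=3, noise_sd=0.0)
    truth = fs.simulate_traits(cfg)[0]
    cube, refs, true_mask = fs.simulate_cube(truth, cfg)
    refl = fs.calibrate_reflectance(cube, refs)
    spectrum = fs.extract_roi_mean(refl, true_mask)
    np.testing.assert_allclose(spectrum.values, clean_spectrum(truth, cfg), atol=1e-9)


def test_background_only_scene_reports_empty_mask():
    cfg = fs.SyntheticConfig(seed=3)
    truth = fs.simulate_traits(cfg)[0]
    # a 2x2 scene has no pixel inside the canopy disk
    cube, refs, true_mask = fs.simulate_cube(truth, cfg, scene_shape=(2, 2))
    assert true_mask.is_empty
    refl = fs.calibrate_reflectance(cube, refs)
    mask = fs.make_mask(refl, threshold=0.45)
    assert mask.is_empty
    with pytest.raises(EmptyROIError):
        fs.extract_roi_mean(refl, mask)
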