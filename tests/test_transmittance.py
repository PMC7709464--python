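"""Transmittance estimation and spectral feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from biotransparency import (
    BandDefinition,
    BandRangeError,
    DegenerateBackgroundError,
    HyperspectralCube,
    IntensitySpectrum,
    TransmittanceSpectrum,
    VISIBLE_BAND,
    band_mean,
    detect_local_minima,
    egg_transmittance,
    estimate_background_spectrum,
    make_grid,
    segment_eggs,
)
from biotransparency.segmentation import BackgroundMask, background_mask
from biotransparency.synthetic import preset_scenes, render_cube

GRID = make_grid(380, 1000, 5)


def dark_disk_cube(tau=0.5, bg=1000.0, frame=(100, 100), r_px=15):
    h, w = frame
    rr, cc = np.mgrid[0:h, 0:w]
    inside = (rr - h / 2) ** 2 + (cc - w / 2) ** 2 <= r_px**2
    img = np.where(inside, tau * bg, bg)
    arr = np.repeat(img[:, :, None], GRID.n_bands, axis=2)
    return HyperspectralCube(arr, GRID, pixel_size_um=2.5)


def full_background(cube):
    return BackgroundMask(np.ones(cube.shape[:2], dtype=bool))


def test_background_spectrum_of_uniform_cube(flat_cube):
    spec = estimate_background_spectrum(flat_cube, full_background(flat_cube))
    assert np.allclose(spec.values, 1000.0)
    assert spec.source == "background"


def test_background_median_robust_to_salt_noise(flat_cube):
    arr = flat_cube.intensities.copy()
    rng = np.random.default_rng(0)
    n = arr.shape[0] * arr.shape[1]
    idx = rng.choice(n, size=n // 100, replace=False)  # 1% outliers
    flat = arr.reshape(n, -1)
    flat[idx] = 5000.0
    cube = HyperspectralCube(arr, flat_cube.grid, flat_cube.pixel_size_um)
    spec = estimate_background_spectrum(cube, full_background(cube))
    assert np.allclose(spec.values, 1000.0)


def test_zero_background_band_is_degenerate(flat_cube):
    arr = flat_cube.intensities.copy()
    arr[:, :, 7] = 0.0
    cube = HyperspectralCube(arr, flat_cube.grid, flat_cube.pixel_size_um)
    with pytest.raises(DegenerateBackgroundError, match="415"):
        estimate_background_spectrum(cube, full_background(cube))


def test_flat_specimen_transmittance():
    cube = dark_disk_cube(tau=0.5)
    region = segment_eggs(cube)[0]
    bg = estimate_background_spectrum(cube, background_mask(cube, [region], 5))
    spec = egg_transmittance(cube, region, bg)
    assert np.allclose(spec.tau, 0.5, atol=1e-12)
    assert spec.n_pixels == region.area_px


def test_specimen_identical_to_background_gives_unit_tau():
    cube = dark_disk_cube(tau=0.5)
    region = segment_eggs(cube)[0]
    # same frame but with the "egg" pixels restored to background level
    flat = HyperspectralCube(np.full_like(cube.intensities, 1000.0),
                             cube.grid, cube.pixel_size_um)
    bg = estimate_background_spectrum(flat, full_background(flat))
    spec = egg_transmittance(flat, region, bg)
    assert np.allclose(spec.tau, 1.0, atol=1e-12)


def test_tau_invariant_under_illumination_rescaling():
    scene = preset_scenes("two_pigment")
    cube, _ = render_cube(scene)
    scaled = HyperspectralCube(cube.intensities * 3.7, cube.grid,
                               cube.pixel_size_um)
    for c1, c2 in [(cube, scaled)]:
        r1, r2 = segment_eggs(c1)[0], segment_eggs(c2)[0]
        b1 = estimate_background_spectrum(c1, background_mask(c1, [r1], 5))
        b2 = estimate_background_spectrum(c2, background_mask(c2, [r2], 5))
        t1 = egg_transmittance(c1, r1, b1)
        t2 = egg_transmittance(c2, r2, b2)
        assert np.allclose(t1.tau, t2.tau, rtol=1e-6)


def test_mean_of_ratios_equals_ratio_of_means_on_flat_background():
    cube = dark_disk_cube(tau=0.31)
    region = segment_eggs(cube)[0]
    bg = estimate_background_spectrum(cube, background_mask(cube, [region], 5))
    spec = egg_transmittance(cube, region, bg)
    ratio_of_means = cube.intensities[region.mask, :].mean(axis=0) / bg.values
    assert np.allclose(spec.tau, ratio_of_means, rtol=1e-12)


def test_central_roi_sees_darker_centre():
    scene = preset_scenes("opaque_like")
    cube, _ = render_cube(scene)
    region = segment_eggs(cube)[0]
    bg = estimate_background_spectrum(cube, background_mask(cube, [region], 5))
    whole = egg_transmittance(cube, region, bg)
    centre = egg_transmittance(cube, region, bg, roi_fraction=0.3)
    # chords are longest through the centre, so the centre transmits less
    assert band_mean(centre, VISIBLE_BAND) < band_mean(whole, VISIBLE_BAND)


def test_band_mean_constant_and_ramp():
    const = TransmittanceSpectrum(GRID, np.full(GRID.n_bands, 0.3))
    assert band_mean(const, VISIBLE_BAND) == pytest.approx(0.3)
    # linear ramp 0 at 400 nm to 1 at 760 nm: symmetric, mean 0.5
    tau = np.clip((GRID.wavelengths - 400) / 360, 0, None)
    ramp = TransmittanceSpectrum(GRID, tau)
    assert band_mean(ramp, VISIBLE_BAND) == pytest.approx(0.5)


def test_band_mean_outside_grid_is_range_error():
    const = TransmittanceSpectrum(GRID, np.full(GRID.n_bands, 0.3))
    with pytest.raises(BandRangeError):
        band_mean(const, BandDefinition("UVB", 300, 350))


@settings(max_examples=50, deadline=None)
@given(st_hyp.integers(min_value=0, max_value=2**32 - 1))
def test_band_mean_is_monotone(seed):
    rng = np.random.default_rng(seed)
    t2 = rng.uniform(0, 1, GRID.n_bands)
    t1 = t2 + rng.uniform(0, 0.2, GRID.n_bands)  # pointwise >= t2
    m1 = band_mean(TransmittanceSpectrum(GRID, t1), VISIBLE_BAND)
    m2 = band_mean(TransmittanceSpectrum(GRID, t2), VISIBLE_BAND)
    assert m1 >= m2


def test_monotone_spectrum_has_no_minima():
    tau = np.linspace(0.2, 0.9, GRID.n_bands)
    spec = TransmittanceSpectrum(GRID, tau)
    assert detect_local_minima(spec) == []


def test_two_pigment_egg_shows_two_minima():
    scene = preset_scenes("two_pigment")
    cube, _ = render_cube(scene)
    region = segment_eggs(cube)[0]
    bg = estimate_background_spectrum(cube, background_mask(cube, [region], 5))
    spec = egg_transmittance(cube, region, bg)
    minima = detect_local_minima(spec, band=VISIBLE_BAND)
    assert len(minima) == 2
    assert minima[0] == pytest.approx(500, abs=5)
    assert minima[1] == pytest.approx(600, abs=5)


def test_single_gaussian_dip_detected():
    lam = GRID.wavelengths
    tau = 0.8 - 0.3 * np.exp(-((lam - 480) ** 2) / (2 * 20**2))
    spec = TransmittanceSpectrum(GRID, tau)
    assert detect_local_minima(spec) == [480.0]


def test_shallow_dip_below_prominence_ignored():
    lam = GRID.wavelengths
    tau = 0.8 - 0.01 * np.exp(-((lam - 480) ** 2) / (2 * 20**2))
    spec = TransmittanceSpectrum(GRID, tau)
    assert detect_local_minima(spec, min_prominence=0.02) == []


def test_background_spectrum_grid_mismatch_rejected(flat_cube):
    other = IntensitySpectrum(make_grid(400, 760, 5), np.ones(73))
    region = segment_eggs(dark_disk_cube())[0]
    with pytest.raises(Exception):
        egg_transmittance(flat_cube, region, other)
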