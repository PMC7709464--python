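"""Forward simulator: spectra, geometry, the closed-form oracle, presets."""

import numpy as np
import pytest
from scipy.integrate import quad

from biotransparency import (
    BandRangeError,
    PigmentBand,
    SceneSpec,
    SyntheticEggSpec,
    VISIBLE_BAND,
    analytic_disk_transmittance,
    chord_path_length,
    make_grid,
    mu_spectrum,
    preset_scenes,
    render_cube,
    solve_baseline_mu,
)
from biotransparency.errors import SceneError
from biotransparency.synthetic import (
    PRESET_NAMES,
    scene_from_json,
    scene_to_json,
)

GRID = make_grid(380, 1000, 5)


def one_egg_scene(**kwargs):
    egg = SyntheticEggSpec(radius_um=100.0, center_px=(100.0, 100.0),
                           pixel_size_um=2.5, **kwargs)
    return SceneSpec(200, 200, GRID, (egg,), background_intensity=1000.0)


def test_mu_spectrum_no_pigments_is_baseline():
    egg = SyntheticEggSpec(100.0, (100, 100), baseline_mu_per_um=0.002)
    assert np.allclose(mu_spectrum(egg, GRID), 0.002)


def test_mu_spectrum_gaussian_band_values():
    egg = SyntheticEggSpec(100.0, (100, 100),
                           pigments=(PigmentBand(500, 20, 0.01),))
    mu = mu_spectrum(egg, GRID)
    i500 = np.argmin(np.abs(GRID.wavelengths - 500))
    i540 = np.argmin(np.abs(GRID.wavelengths - 540))
    assert mu[i500] == pytest.approx(0.01)
    assert mu[i540] == pytest.approx(0.01 * np.exp(-2), rel=1e-9)  # 2 sigma


def test_mu_spectrum_two_bands_two_maxima():
    egg = SyntheticEggSpec(100.0, (100, 100),
                           pigments=(PigmentBand(500, 20, 0.01),
                                     PigmentBand(600, 20, 0.01)))
    mu = mu_spectrum(egg, GRID)
    interior = (mu[1:-1] > mu[:-2]) & (mu[1:-1] > mu[2:])
    peaks = GRID.wavelengths[1:-1][interior]
    assert list(peaks) == [500.0, 600.0]


@pytest.mark.parametrize("radius,rho,expected",
                         [(100, 0, 200), (100, 100, 0), (100, 60, 160)])
def test_chord_path_length(radius, rho, expected):
    assert chord_path_length(radius, rho) == pytest.approx(expected)


def test_chord_rejects_offset_beyond_radius():
    with pytest.raises(BandRangeError):
        chord_path_length(100, 101)


@pytest.mark.parametrize("mu,r,R,expected", [
    (0.0, 100, 0.0, 1.0),
    (0.0, 100, 0.04, 0.96),
    (0.01, 100, 0.0, (1 - 3 * np.exp(-2)) / 2),  # a = 2: [1-(1+2)e^-2]/2
])
def test_analytic_disk_transmittance_known_values(mu, r, R, expected):
    assert analytic_disk_transmittance(mu, r, R) == pytest.approx(expected,
                                                                  rel=1e-12)


def test_analytic_formula_matches_chord_quadrature():
    """T = (2/r^2) * int_0^r exp(-2 mu sqrt(r^2-rho^2)) rho drho, checked
    across mu*r in [0, 5]."""
    r = 123.4
    for mur in np.linspace(0.0, 5.0, 21):
        mu = mur / r
        num, _ = quad(
            lambda rho: np.exp(-2 * mu * np.sqrt(r**2 - rho**2)) * rho,
            0, r, epsabs=1e-14, epsrel=1e-13)
        expected = 2 * num / r**2
        got = analytic_disk_transmittance(mu, r)
        assert got == pytest.approx(expected, rel=1e-8)


def test_solver_inverts_disk_transmittance():
    for target in (0.1, 0.5, 0.9):
        mu = solve_baseline_mu(target, 100.0)
        assert analytic_disk_transmittance(mu, 100.0) == pytest.approx(
            target, abs=1e-10)


def test_transparent_limit_indistinguishable_from_background():
    cube, _ = render_cube(one_egg_scene(baseline_mu_per_um=0.0))
    assert np.allclose(cube.intensities, 1000.0)


def test_render_matches_analytic_oracle_per_band():
    """Mean tau over the true disk mask equals the closed form within 1%."""
    scene = one_egg_scene(baseline_mu_per_um=0.003,
                          pigments=(PigmentBand(500, 25, 0.006),))
    cube, (truth,) = render_cube(scene)
    rr, cc = np.mgrid[0:200, 0:200]
    r_px = 100.0 / 2.5
    inside = np.hypot(rr - 100, cc - 100) <= r_px
    tau = cube.intensities[inside, :].mean(axis=0) / 1000.0
    assert np.allclose(tau, truth.analytic_tau, rtol=0.01)


def test_render_is_deterministic_given_seed():
    scene = preset_scenes("transparent_like", seed=5, noise_sd_counts=30.0)
    c1, _ = render_cube(scene)
    c2, _ = render_cube(scene)
    assert np.array_equal(c1.intensities, c2.intensities)


def test_different_seeds_differ():
    a, _ = render_cube(preset_scenes("opaque_like", seed=1, noise_sd_counts=30.0))
    b, _ = render_cube(preset_scenes("opaque_like", seed=2, noise_sd_counts=30.0))
    assert not np.array_equal(a.intensities, b.intensities)


def test_edge_bright_tau_nondecreasing_in_radius():
    scene = one_egg_scene(baseline_mu_per_um=0.005)
    cube, _ = render_cube(scene)
    band = cube.intensities[:, :, 40] / 1000.0
    rr, cc = np.mgrid[0:200, 0:200]
    rho = np.hypot(rr - 100, cc - 100)
    inside = rho <= 100.0 / 2.5
    order = np.argsort(rho[inside], kind="stable")
    tau_sorted = band[inside][order]
    assert np.all(np.diff(tau_sorted) >= -1e-6)


def test_slab_assumption_underestimates_mu_and_bias_grows():
    """Treating the egg as a slab of thickness 2r underestimates the true
    mu, increasingly so as mu*r grows."""
    r = 100.0
    biases = []
    for mur in (0.2, 0.5, 1.0, 2.0):
        mu = mur / r
        tau_bar = analytic_disk_transmittance(mu, r)
        mu_slab = -np.log(tau_bar) / (2 * r)
        assert mu_slab < mu
        biases.append((mu - mu_slab) / mu)
    assert np.all(np.diff(biases) > 0)


def test_overlapping_eggs_rejected():
    eggs = (SyntheticEggSpec(100.0, (100, 80), pixel_size_um=2.5),
            SyntheticEggSpec(100.0, (100, 120), pixel_size_um=2.5))
    with pytest.raises(SceneError):
        SceneSpec(200, 200, GRID, eggs)


def test_egg_must_fit_in_frame():
    with pytest.raises(SceneError):
        SceneSpec(50, 50, GRID,
                  (SyntheticEggSpec(100.0, (25, 25), pixel_size_um=2.5),))


def test_bt_sweep_ground_truths_hit_targets():
    scene = preset_scenes("bt_sweep")
    _, truths = render_cube(scene)
    bts = sorted(t.bio_transparency_pct for t in truths)
    assert np.allclose(bts, np.arange(10, 100, 10), atol=0.1)


def test_transparent_preset_is_transparent():
    _, (truth,) = render_cube(preset_scenes("transparent_like"))
    assert truth.bio_transparency_pct >= 85.0


def test_size_sweep_covers_reported_diameters():
    scene = preset_scenes("size_sweep")
    assert sorted(e.diameter_um for e in scene.eggs) == [120.0, 200.0,
                                                         300.0, 381.0]


def test_unknown_preset_rejected():
    with pytest.raises(Exception):
        preset_scenes("nope")
    assert "bt_sweep" in PRESET_NAMES


def test_scene_json_roundtrip(tmp_path):
    scene = preset_scenes("two_pigment", seed=9, noise_sd_counts=12.5)
    path = scene_to_json(scene, tmp_path / "scene.json")
    back = scene_from_json(path)
    assert back.eggs == scene.eggs
    assert back.seed == scene.seed
    assert back.noise_sd_counts == scene.noise_sd_counts
    c1, _ = render_cube(scene)
    c2, _ = render_cube(back)
    assert np.array_equal(c1.intensities, c2.intensities)
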