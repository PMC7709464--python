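"""Forward optical simulator: hyperspectral cubes of pigmented spherical eggs.

The imaging data behind the transparency survey are not deposited, so this
module renders physically motivated phantoms with *analytic* ground truth.
An egg is a homogeneous attenuating sphere of radius r immersed in seawater
on a bright background.  Collimated light crossing the sphere at radial
offset rho travels a chord of length l(rho) = 2*sqrt(r^2 - rho^2) and is
attenuated by exp(-mu(lambda) * l(rho)); a wavelength-independent fraction
R is additionally lost to surface reflection.  The total attenuation
coefficient mu(lambda) is a baseline floor plus Gaussian pigment absorption
bands -- scattering is folded into mu, matching what a transmission
measurement can actually distinguish (nothing).

The area-averaged transmittance of the projected disk has the closed form

    T(mu) = (1 - R) * [1 - (1 + 2 mu r) e^{-2 mu r}] / (2 mu^2 r^2),

with the continuous limit (1 - R) at mu = 0.  Ground truth is always this
analytic value, never a measurement on the rendered image, so pipeline
tests against it cannot be circular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import BandRangeError, SceneError, ValidationError
from .spectral_io import (
    HyperspectralCube,
    VISIBLE_BAND,
    WavelengthGrid,
    make_grid,
)

__all__ = [
    "PigmentBand",
    "SyntheticEggSpec",
    "SceneSpec",
    "GroundTruth",
    "mu_spectrum",
    "chord_path_length",
    "analytic_disk_transmittance",
    "solve_baseline_mu",
    "render_cube",
    "preset_scenes",
    "PRESET_NAMES",
    "scene_to_json",
    "scene_from_json",
    "ground_truth_to_csv",
]


@dataclass(frozen=True)
class PigmentBand:
    """Gaussian absorption band: peak centre (nm), SD width (nm), and the
    peak contribution to mu in 1/um."""

    center_nm: float
    width_nm: float
    amplitude_per_um: float

    def __post_init__(self):
        if not self.width_nm > 0:
            raise ValidationError("pigment width_nm must be > 0")
        if self.amplitude_per_um < 0:
            raise ValidationError("pigment amplitude must be >= 0")


@dataclass(frozen=True)
class SyntheticEggSpec:
    """One spherical egg: geometry, pigments, surface reflection."""

    radius_um: float
    center_px: tuple[float, float]
    pigments: tuple[PigmentBand, ...] = ()
    baseline_mu_per_um: float = 0.0
    reflection_loss: float = 0.0
    pixel_size_um: float = 2.5

    def __post_init__(self):
        if not self.radius_um > 0:
            raise ValidationError("radius_um must be > 0")
        if not 0 <= self.reflection_loss < 1:
            raise ValidationError("reflection_loss must be in [0, 1)")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")

    @property
    def radius_px(self) -> float:
        return self.radius_um / self.pixel_size_um

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic frame: geometry, illumination, sensor noise."""

    height_px: int
    width_px: int
    grid: WavelengthGrid
    eggs: tuple[SyntheticEggSpec, ...]
    background_intensity: float | np.ndarray = 1000.0
    illumination_gradient: float = 0.0
    noise_sd_counts: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_counts < 0:
            raise ValidationError("noise_sd_counts must be >= 0")
        for egg in self.eggs:
            r, c = egg.center_px
            rad = egg.radius_px
            if (r - rad < 1 or c - rad < 1
                    or r + rad > self.height_px - 2 or c + rad > self.width_px - 2):
                raise SceneError(
                    f"egg at {egg.center_px} with radius {rad:.1f} px does not "
                    f"fit inside the {self.height_px}x{self.width_px} frame "
                    "with margin"
                )
        for i, a in enumerate(self.eggs):
            for b in self.eggs[i + 1:]:
                d = np.hypot(a.center_px[0] - b.center_px[0],
                             a.center_px[1] - b.center_px[1])
                if d < a.radius_px + b.radius_px + 2:
                    raise SceneError(
                        f"eggs at {a.center_px} and {b.center_px} overlap "
                        "(after 2-px dilation)"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic expectations for one rendered egg."""

    egg_index: int
    diameter_um: float
    mu_spectrum: np.ndarray = field(repr=False)
    analytic_tau: np.ndarray = field(repr=False)
    bio_transparency_pct: float = 0.0
    mu_visible_per_um: float = 0.0


def mu_spectrum(spec: SyntheticEggSpec, grid: WavelengthGrid) -> np.ndarray:
    """mu(lambda) = baseline + sum_k amp_k * exp(-(lambda-c_k)^2 / (2 w_k^2))."""
    lam = grid.wavelengths
    mu = np.full(grid.n_bands, spec.baseline_mu_per_um, dtype=np.float64)
    for p in spec.pigments:
        mu += p.amplitude_per_um * np.exp(-((lam - p.center_nm) ** 2)
                                          / (2.0 * p.width_nm**2))
    return mu


def chord_path_length(radius_um: float, rho_um: float | np.ndarray) -> float | np.ndarray:
    """Path length through a sphere at radial offset rho: 2*sqrt(r^2 - rho^2)."""
    rho = np.asarray(rho_um, dtype=np.float64)
    if np.any(rho < 0) or np.any(rho > radius_um):
        raise BandRangeError(
            f"radial offset must lie in [0, {radius_um}] um"
        )
    out = 2.0 * np.sqrt(radius_um**2 - rho**2)
    return float(out) if np.isscalar(rho_um) else out


def analytic_disk_transmittance(mu, radius_um: float,
                                reflection_loss: float = 0.0):
    """Area-averaged transmittance of the sphere's projected disk.

    T(mu) = (1-R) [1 - (1 + a) e^{-a}] / (a^2 / 2) with a = 2 mu r; the
    mu -> 0 limit is (1-R).  A short series keeps the evaluation stable
    for a << 1, where the closed form loses precision to cancellation.
    """
    if not radius_um > 0:
        raise ValidationError("radius_um must be > 0")
    mu_arr = np.asarray(mu, dtype=np.float64)
    if np.any(mu_arr < 0):
        raise ValidationError("mu must be >= 0")
    a = 2.0 * mu_arr * radius_um
    out = np.empty_like(a)
    small = a < 1e-4
    # series of [1-(1+a)e^-a]/(a^2/2) = 1 - 2a/3 + a^2/4 - a^3/15 + ...
    asm = a[small]
    out[small] = 1.0 - 2.0 * asm / 3.0 + asm**2 / 4.0 - asm**3 / 15.0
    ab = a[~small]
    out[~small] = (1.0 - (1.0 + ab) * np.exp(-ab)) / (ab**2 / 2.0)
    out *= 1.0 - reflection_loss
    return float(out) if np.isscalar(mu) else out


def solve_baseline_mu(target_tau: float, radius_um: float,
                      reflection_loss: float = 0.0) -> float:
    """Invert the disk-transmittance formula: the flat mu whose
    area-averaged transmittance equals ``target_tau``."""
    if not 0 < target_tau < (1.0 - reflection_loss):
        raise ValidationError(
            f"target transmittance {target_tau} unreachable with R={reflection_loss}"
        )
    f = lambda m: analytic_disk_transmittance(m, radius_um, reflection_loss) - target_tau
    hi = 1.0 / radius_um
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14))


def _egg_ground_truth(index: int, egg: SyntheticEggSpec,
                      grid: WavelengthGrid) -> GroundTruth:
    mu = mu_spectrum(egg, grid)
    tau = analytic_disk_transmittance(mu, egg.radius_um, egg.reflection_loss)
    vis = VISIBLE_BAND.selector(grid)
    return GroundTruth(
        egg_index=index,
        diameter_um=egg.diameter_um,
        mu_spectrum=mu,
        analytic_tau=tau,
        bio_transparency_pct=100.0 * float(tau[vis].mean()),
        mu_visible_per_um=float(mu[vis].mean()),
    )


def render_cube(scene: SceneSpec) -> tuple[HyperspectralCube, list[GroundTruth]]:
    """Render a scene to a cube plus per-egg analytic ground truth.

    Background pixels carry the incident spectrum I0(lambda), optionally
    with a linear left-to-right illumination gradient; egg pixels at
    radial offset rho carry I0 * (1-R) * exp(-mu(lambda) * l(rho)).  The
    eggs sit in the same illumination field as the background, so the
    gradient multiplies both.  Additive Gaussian sensor noise (SD in
    counts) is drawn once for the whole frame and the result is clipped
    at zero; rendering is deterministic given the scene seed.
    """
    h, w = scene.height_px, scene.width_px
    grid = scene.grid
    nb = grid.n_bands
    i0 = np.broadcast_to(
        np.asarray(scene.background_intensity, dtype=np.float64).reshape(-1),
        (nb,),
    ).astype(np.float64)
    if np.asarray(scene.background_intensity).size not in (1, nb):
        raise ValidationError("background_intensity must be scalar or per-band")

    illum = np.ones((h, w), dtype=np.float64)
    if scene.illumination_gradient:
        cols = np.arange(w, dtype=np.float64)
        ramp = (cols / max(w - 1, 1)) - 0.5
        illum *= 1.0 + scene.illumination_gradient * ramp[np.newaxis, :]

    # transmission factor per pixel per band; background transmits fully
    cube = np.empty((h, w, nb), dtype=np.float32)
    cube[:] = (illum[:, :, np.newaxis] * i0[np.newaxis, np.newaxis, :]).astype(
        np.float32)

    truths: list[GroundTruth] = []
    for index, egg in enumerate(scene.eggs):
        mu = mu_spectrum(egg, grid)
        r_px = egg.radius_px
        cr, cc = egg.center_px
        r0 = max(0, int(np.floor(cr - r_px)) - 1)
        r1 = min(h, int(np.ceil(cr + r_px)) + 2)
        c0 = max(0, int(np.floor(cc - r_px)) - 1)
        c1 = min(w, int(np.ceil(cc + r_px)) + 2)
        rr, cc_idx = np.mgrid[r0:r1, c0:c1]
        rho_px = np.hypot(rr - cr, cc_idx - cc)
        inside = rho_px <= r_px
        rho_um = rho_px[inside] * egg.pixel_size_um
        path = 2.0 * np.sqrt(np.maximum(egg.radius_um**2 - rho_um**2, 0.0))
        trans = (1.0 - egg.reflection_loss) * np.exp(
            -np.outer(path, mu))  # (n_inside, B)
        local_i0 = illum[r0:r1, c0:c1][inside][:, np.newaxis] * i0[np.newaxis, :]
        block = cube[r0:r1, c0:c1]
        block[inside] = (local_i0 * trans).astype(np.float32)
        truths.append(_egg_ground_truth(index, egg, grid))

    if scene.noise_sd_counts > 0:
        rng = np.random.default_rng(scene.seed)
        noise = rng.standard_normal(cube.shape, dtype=np.float32)
        cube = cube + scene.noise_sd_counts * noise
        np.maximum(cube, 0.0, out=cube)

    hcube = HyperspectralCube(
        cube, grid, scene.eggs[0].pixel_size_um if scene.eggs else 1.0,
        metadata={"synthetic": True, "seed": scene.seed},
    )
    return hcube, truths


# ---------------------------------------------------------------------------
# Presets spanning the reported study conditions: bio-transparency across
# 10-90% and egg diameters from 120 to 381 um.

PRESET_NAMES = ("transparent_like", "opaque_like", "two_pigment",
                "size_sweep", "bt_sweep")

_DEFAULT_BG = 1000.0
_DEFAULT_PX = 2.5  # um/pixel: a 10x objective scale that resolves a 120-um egg


def preset_scenes(name: str, seed: int = 0, noise_sd_counts: float = 0.0,
                  grid: WavelengthGrid | None = None) -> SceneSpec:
    """Deterministic study-condition scenes by name.

    ``transparent_like`` / ``opaque_like``: one egg near the top / bottom
    of the observed transparency range.  ``two_pigment``: one egg with
    absorption bands at 500 and 600 nm (the double-dip phenotype).
    ``size_sweep``: four eggs at the reported diameter extremes
    {120, 200, 300, 381} um under one fixed mu(lambda).  ``bt_sweep``:
    nine equal-size eggs whose ground-truth bio-transparency is
    root-solved to 10, 20, ..., 90%.
    """
    grid = grid or make_grid(380, 1000, 5)
    if name == "transparent_like":
        radius = 100.0
        base = solve_baseline_mu(0.90, radius)
        eggs = (SyntheticEggSpec(radius, (100.0, 100.0),
                                 pigments=(PigmentBand(490.0, 25.0, base * 0.5),),
                                 baseline_mu_per_um=base,
                                 pixel_size_um=_DEFAULT_PX),)
        return SceneSpec(200, 200, grid, eggs, _DEFAULT_BG,
                         noise_sd_counts=noise_sd_counts, seed=seed)
    if name == "opaque_like":
        radius = 100.0
        base = solve_baseline_mu(0.15, radius)
        eggs = (SyntheticEggSpec(radius, (100.0, 100.0),
                                 baseline_mu_per_um=base,
                                 pixel_size_um=_DEFAULT_PX),)
        return SceneSpec(200, 200, grid, eggs, _DEFAULT_BG,
                         noise_sd_counts=noise_sd_counts, seed=seed)
    if name == "two_pigment":
        radius = 100.0
        eggs = (SyntheticEggSpec(
            radius, (100.0, 100.0),
            pigments=(PigmentBand(500.0, 20.0, 0.004),
                      PigmentBand(600.0, 20.0, 0.004)),
            baseline_mu_per_um=0.001,
            pixel_size_um=_DEFAULT_PX),)
        return SceneSpec(200, 200, grid, eggs, _DEFAULT_BG,
                         noise_sd_counts=noise_sd_counts, seed=seed)
    if name == "size_sweep":
        diameters = (120.0, 200.0, 300.0, 381.0)
        mu0 = 0.004  # mid-range opacity at these sizes
        eggs = []
        col = 0.0
        for d in diameters:
            r_px = (d / 2.0) / _DEFAULT_PX
            col += r_px + 14.0
            eggs.append(SyntheticEggSpec(d / 2.0, (110.0, col),
                                         baseline_mu_per_um=mu0,
                                         pixel_size_um=_DEFAULT_PX))
            col += r_px
        return SceneSpec(220, int(col + 14.0), grid, tuple(eggs), _DEFAULT_BG,
                         noise_sd_counts=noise_sd_counts, seed=seed)
    if name == "bt_sweep":
        radius = 100.0
        r_px = radius / _DEFAULT_PX  # 40 px
        targets = [0.10 + 0.10 * k for k in range(9)]
        eggs = []
        for k, t in enumerate(targets):
            base = solve_baseline_mu(t, radius)
            row = 55.0 + 95.0 * (k // 3)
            col = 55.0 + 95.0 * (k % 3)
            eggs.append(SyntheticEggSpec(radius, (row, col),
                                         baseline_mu_per_um=base,
                                         pixel_size_um=_DEFAULT_PX))
        return SceneSpec(300, 300, grid, tuple(eggs), _DEFAULT_BG,
                         noise_sd_counts=noise_sd_counts, seed=seed)
    raise ValidationError(
        f"unknown preset {name!r}; choose one of {PRESET_NAMES}"
    )


# ---------------------------------------------------------------------------
# Serialization

def scene_to_json(scene: SceneSpec, path: str | Path) -> Path:
    path = Path(path)
    d = {
        "height_px": scene.height_px,
        "width_px": scene.width_px,
        "grid": {"start_nm": scene.grid.start_nm, "stop_nm": scene.grid.stop_nm,
                 "step_nm": scene.grid.step_nm},
        "eggs": [
            {
                "radius_um": e.radius_um,
                "center_px": list(e.center_px),
                "pigments": [asdict(p) for p in e.pigments],
                "baseline_mu_per_um": e.baseline_mu_per_um,
                "reflection_loss": e.reflection_loss,
                "pixel_size_um": e.pixel_size_um,
            }
            for e in scene.eggs
        ],
        "background_intensity": (
            scene.background_intensity
            if np.isscalar(scene.background_intensity)
            else list(np.asarray(scene.background_intensity, dtype=float))
        ),
        "illumination_gradient": scene.illumination_gradient,
        "noise_sd_counts": scene.noise_sd_counts,
        "seed": scene.seed,
    }
    path.write_text(json.dumps(d, indent=1))
    return path


def scene_from_json(path: str | Path) -> SceneSpec:
    d = json.loads(Path(path).read_text())
    grid = make_grid(**d["grid"])
    eggs = tuple(
        SyntheticEggSpec(
            radius_um=e["radius_um"],
            center_px=tuple(e["center_px"]),
            pigments=tuple(PigmentBand(**p) for p in e["pigments"]),
            baseline_mu_per_um=e["baseline_mu_per_um"],
            reflection_loss=e["reflection_loss"],
            pixel_size_um=e["pixel_size_um"],
        )
        for e in d["eggs"]
    )
    bg = d["background_intensity"]
    return SceneSpec(
        height_px=d["height_px"], width_px=d["width_px"], grid=grid, eggs=eggs,
        background_intensity=bg if np.isscalar(bg) else np.asarray(bg),
        illumination_gradient=d["illumination_gradient"],
        noise_sd_counts=d["noise_sd_counts"], seed=d["seed"],
    )


def ground_truth_to_csv(truths: list[GroundTruth], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "egg_index": t.egg_index,
                "diameter_um": t.diameter_um,
                "bio_transparency_pct_truth": t.bio_transparency_pct,
                "mu_visible_truth": t.mu_visible_per_um,
            }
            for t in truths
        ]
    ).to_csv(path, index=False)
    return path
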