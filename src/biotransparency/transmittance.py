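"""Per-egg transmittance spectra and spectral feature extraction.

Transmittance is the ratio tau(lambda) = I / I0 between light transmitted
through the specimen and the incident light, estimated per wavelength as
the ratio of egg-pixel intensity to the surrounding seawater background.
Because it is a ratio, it is invariant to global illumination rescaling.
tau is never clipped at 1: clipping would bias the transparency statistic
upward under noise, so out-of-range values are merely QC-flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import BandRangeError, DegenerateBackgroundError, ValidationError
from .segmentation import BackgroundMask, EggRegion
from .spectral_io import BandDefinition, HyperspectralCube, WavelengthGrid

logger = logging.getLogger(__name__)

__all__ = [
    "IntensitySpectrum",
    "TransmittanceSpectrum",
    "estimate_background_spectrum",
    "egg_transmittance",
    "band_mean",
    "detect_local_minima",
    "spectra_to_long_csv",
    "spectra_to_wide_csv",
]

#: tau above this is physically implausible and gets a QC flag
TAU_QC_LIMIT = 1.05


@dataclass(frozen=True)
class IntensitySpectrum:
    """Per-band intensity in sensor counts, for background or specimen."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)
    source: str = "background"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.grid.n_bands,):
            raise ValidationError(
                f"spectrum has {v.shape} values for a {self.grid.n_bands}-band grid"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("intensity spectrum contains non-finite values")
        if self.source == "background" and v.min() <= 0:
            bad = self.grid.wavelengths[v <= 0]
            raise DegenerateBackgroundError(
                f"background intensity nonpositive at {bad[0]:g} nm "
                f"({len(bad)} band(s))"
            )
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TransmittanceSpectrum:
    """tau(lambda) for one egg, plus how many pixels were averaged."""

    grid: WavelengthGrid
    tau: np.ndarray = field(repr=False)
    egg_id: str = ""
    n_pixels: int = 0

    def __post_init__(self):
        t = np.asarray(self.tau, dtype=np.float64)
        if t.shape != (self.grid.n_bands,):
            raise ValidationError(
                f"tau has {t.shape} values for a {self.grid.n_bands}-band grid"
            )
        if not np.all(np.isfinite(t)):
            raise ValidationError("tau contains non-finite values")
        if t.min() < 0:
            raise ValidationError("tau must be nonnegative")
        object.__setattr__(self, "tau", t)

    @property
    def qc_bands_above_unity(self) -> int:
        """Number of bands with tau exceeding the physical limit."""
        return int(np.sum(self.tau > TAU_QC_LIMIT))


def estimate_background_spectrum(cube: HyperspectralCube,
                                 bg: BackgroundMask) -> IntensitySpectrum:
    """Per-band **median** intensity over background pixels.

    The median makes the incident-light estimate robust to stray dark
    specks (debris, dust) in the nominal background.
    """
    if not bg.mask.any():
        raise ValidationError("background mask is empty")
    values = np.median(cube.intensities[bg.mask, :], axis=0)
    return IntensitySpectrum(cube.grid, values, source="background")


def egg_transmittance(cube: HyperspectralCube, region: EggRegion,
                      background: IntensitySpectrum,
                      roi_fraction: float = 1.0) -> TransmittanceSpectrum:
    """tau(lambda) for one egg: mean over mask pixels of I(pixel)/I0.

    With a per-band-constant I0 the mean of per-pixel ratios equals the
    ratio of means, but the former generalizes if a per-pixel flat field
    is ever substituted.  ``roi_fraction`` < 1 restricts the average to a
    central disk of that fraction of the equivalent radius (sensitivity
    analysis: the egg rim transmits more than its centre).
    """
    if background.grid != cube.grid:
        raise ValidationError("background spectrum grid does not match cube grid")
    mask = region.mask
    if roi_fraction < 1.0:
        if not 0 < roi_fraction:
            raise ValidationError("roi_fraction must be in (0, 1]")
        h, w = mask.shape
        rr, cc = np.mgrid[0:h, 0:w]
        radius_px = np.sqrt(region.area_px / np.pi) * roi_fraction
        central = (rr - region.centroid[0]) ** 2 + (cc - region.centroid[1]) ** 2 \
            <= radius_px**2
        mask = mask & central
        if not mask.any():
            raise ValidationError("central ROI contains no pixels; increase roi_fraction")
    pix = cube.intensities[mask, :]
    tau = (pix / background.values[np.newaxis, :]).mean(axis=0)
    spec = TransmittanceSpectrum(cube.grid, tau, egg_id=str(region.label),
                                 n_pixels=int(mask.sum()))
    if spec.qc_bands_above_unity:
        logger.warning("egg %s: tau > %.2f in %d band(s)", spec.egg_id,
                       TAU_QC_LIMIT, spec.qc_bands_above_unity)
    return spec


def band_mean(spectrum: TransmittanceSpectrum, band: BandDefinition) -> float:
    """Unweighted mean of tau over grid bands inside ``band`` (inclusive)."""
    sel = band.selector(spectrum.grid)
    if not sel.any():
        raise BandRangeError(
            f"band {band.name} [{band.low_nm}, {band.high_nm}] nm does not "
            f"overlap grid [{spectrum.grid.start_nm}, {spectrum.grid.stop_nm}] nm"
        )
    return float(spectrum.tau[sel].mean())


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return x.copy()
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def detect_local_minima(spectrum: TransmittanceSpectrum,
                        smooth_window_bands: int = 3,
                        min_prominence: float = 0.02,
                        band: BandDefinition | None = None) -> list[float]:
    """Wavelengths (nm) of prominent local minima of tau within ``band``.

    The spectrum is smoothed with a centred moving average of
    ``smooth_window_bands`` points, then strict local minima are kept when
    their prominence -- the drop below the lower of the two flanking
    maxima -- reaches ``min_prominence``.  Absorption dips of egg pigments
    show up as such minima (e.g. carotenoid-like dips near 500 nm).
    """
    if smooth_window_bands < 1 or smooth_window_bands % 2 == 0:
        raise ValidationError("smooth_window_bands must be an odd count >= 1")
    smoothed = _moving_average(spectrum.tau, smooth_window_bands)
    # minima of tau are peaks of -tau; find_peaks prominence matches the
    # flanking-maxima definition on the inverted signal
    idx, _ = find_peaks(-smoothed, prominence=min_prominence)
    wavelengths = spectrum.grid.wavelengths[idx]
    if band is not None:
        keep = (wavelengths >= band.low_nm) & (wavelengths <= band.high_nm)
        wavelengths = wavelengths[keep]
    return [float(w) for w in sorted(wavelengths)]


def spectra_to_long_csv(spectra: list[TransmittanceSpectrum],
                        path: str | Path) -> Path:
    """Long-format export: one row per (egg, wavelength)."""
    rows = [
        {"egg_id": s.egg_id, "wavelength_nm": w, "tau": t}
        for s in spectra
        for w, t in zip(s.grid.wavelengths, s.tau)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["egg_id", "wavelength_nm", "tau"]).to_csv(
        path, index=False)
    return path


def spectra_to_wide_csv(spectra: list[TransmittanceSpectrum],
                        path: str | Path) -> Path:
    """Wide-format export: one row per egg, one column per band."""
    path = Path(path)
    if not spectra:
        pd.DataFrame({"egg_id": []}).to_csv(path, index=False)
        return path
    grid = spectra[0].grid
    cols = {"egg_id": [s.egg_id for s in spectra]}
    for i, w in enumerate(grid.wavelengths):
        cols[f"tau_{w:g}nm"] = [s.tau[i] for s in spectra]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
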