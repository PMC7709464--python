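"""Wavelength grids, hyperspectral cubes and their file formats.

A hyperspectral transmission measurement is an H x W image stack with one
full spectrum per pixel.  The study conditions sample 380-1000 nm every
5 nm, giving 125 bands.  Two on-disk dialects are supported:

* ``envi`` -- the minimal common ENVI raster dialect: an ASCII ``.hdr``
  header next to a flat binary file, with BSQ/BIL/BIP interleave and a
  ``wavelength`` list.
* ``fixture`` -- a bit-exact JSON sidecar (``<name>.json``) plus a
  row-major little-endian float32 payload (``<name>.bin``).

Intensities are held as floating point regardless of the file bit depth.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import BandRangeError, FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthGrid",
    "HyperspectralCube",
    "BandDefinition",
    "UVA_BAND",
    "VISIBLE_BAND",
    "NIR_BAND",
    "make_grid",
    "band_index",
    "read_cube",
    "write_cube",
]

# spacing regularity tolerance, in nm
_SPACING_TOL = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis shared by all spectra and cubes.

    Attributes
    ----------
    start_nm, stop_nm, step_nm : float
        Grid limits and increment in nanometres.
    wavelengths : numpy.ndarray
        Band-centre wavelengths ``start, start+step, ..., stop``.
    """

    start_nm: float
    stop_nm: float
    step_nm: float
    wavelengths: np.ndarray = field(repr=False)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def __eq__(self, other) -> bool:  # ndarray field breaks default eq
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.stop_nm == other.stop_nm
            and self.step_nm == other.step_nm
            and np.array_equal(self.wavelengths, other.wavelengths)
        )


@dataclass(frozen=True)
class BandDefinition:
    """A named wavelength interval, inclusive on both edges."""

    name: str
    low_nm: float
    high_nm: float

    def __post_init__(self):
        if not self.low_nm < self.high_nm:
            raise ValidationError(
                f"band {self.name!r}: low_nm ({self.low_nm}) must be < high_nm ({self.high_nm})"
            )

    def selector(self, grid: WavelengthGrid) -> np.ndarray:
        """Boolean mask of grid bands with ``low_nm <= lambda <= high_nm``."""
        w = grid.wavelengths
        return (w >= self.low_nm - _SPACING_TOL) & (w <= self.high_nm + _SPACING_TOL)


#: Conventional band splits of the sampled 380-1000 nm range.  The visible
#: band [400, 760] nm is the one the bio-transparency statistic averages over.
UVA_BAND = BandDefinition("UVA", 380.0, 400.0)
VISIBLE_BAND = BandDefinition("VIS", 400.0, 760.0)
NIR_BAND = BandDefinition("NIR", 760.0, 1000.0)


@dataclass
class HyperspectralCube:
    """H x W x B nonnegative intensity stack with wavelength + pixel metadata.

    ``intensities`` are in arbitrary sensor counts; transmittance is always
    a ratio so absolute calibration is never needed.
    """

    intensities: np.ndarray
    grid: WavelengthGrid
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValidationError(
                f"intensities must be 3-D (H, W, B); got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        h, w, b = arr.shape
        if h < 1 or w < 1:
            raise ValidationError("cube must have H >= 1 and W >= 1")
        if b != self.grid.n_bands:
            raise ValidationError(
                f"cube has {b} bands but grid has {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("intensities contain NaN or infinite values")
        if arr.min() < 0:
            raise ValidationError("intensities must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build an evenly spaced wavelength grid.

    ``step_nm`` must divide ``stop_nm - start_nm`` exactly; the default
    study grid ``make_grid(380, 1000, 5)`` has 125 bands.
    """
    if step_nm <= 0:
        raise ValidationError(f"step_nm must be > 0, got {step_nm}")
    if start_nm <= 0:
        raise ValidationError(f"start_nm must be > 0, got {start_nm}")
    if stop_nm <= start_nm:
        raise ValidationError(
            f"stop_nm ({stop_nm}) must be greater than start_nm ({start_nm})"
        )
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > _SPACING_TOL:
        raise ValidationError(
            f"step_nm ({step_nm}) does not divide stop_nm - start_nm ({span}) exactly"
        )
    n = int(round(n_steps)) + 1
    wavelengths = start_nm + step_nm * np.arange(n, dtype=np.float64)
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), wavelengths)


def _grid_from_wavelengths(wavelengths: np.ndarray) -> WavelengthGrid:
    """Validate even spacing and wrap a raw wavelength list into a grid."""
    w = np.asarray(wavelengths, dtype=np.float64)
    if w.ndim != 1 or len(w) < 2:
        raise FormatError("wavelength list must be 1-D with at least two entries")
    diffs = np.diff(w)
    if np.any(diffs <= 0):
        raise FormatError("wavelengths must be strictly increasing")
    step = diffs[0]
    if np.max(np.abs(diffs - step)) > _SPACING_TOL * max(1.0, step):
        raise FormatError(
            f"wavelengths are unevenly spaced (band spacings range "
            f"{diffs.min():g}-{diffs.max():g} nm); refusing to coerce"
        )
    return WavelengthGrid(float(w[0]), float(w[-1]), float(step), w)


def band_index(grid: WavelengthGrid, wavelength_nm: float) -> int:
    """Index of the band centre nearest ``wavelength_nm``.

    The wavelength must lie within ``[start_nm, stop_nm]``; an on-grid
    wavelength maps to its exact band.
    """
    if not (grid.start_nm <= wavelength_nm <= grid.stop_nm):
        raise BandRangeError(
            f"wavelength {wavelength_nm} nm outside grid "
            f"[{grid.start_nm}, {grid.stop_nm}] nm"
        )
    return int(round((wavelength_nm - grid.start_nm) / grid.step_nm))


# ---------------------------------------------------------------------------
# ENVI dialect

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_KNOWN_HDR_KEYS = {
    "samples", "lines", "bands", "data type", "interleave", "byte order",
    "wavelength", "wavelength units", "header offset", "file type",
    "pixel size um", "description",
}


def _parse_envi_header(text: str) -> dict:
    """Parse the ASCII key = value / key = { ... } ENVI header grammar."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("missing ENVI magic line in header")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # `key = value` or `key = { multi, line, list }`
    pattern = re.compile(r"^\s*([\w ][\w \-]*?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        fields[key] = m.group(2).strip()
    for key in fields:
        if key not in _KNOWN_HDR_KEYS:
            logger.warning("ignoring unrecognized ENVI header key %r", key)
    return fields


def _read_envi(path: Path) -> HyperspectralCube:
    hdr_path = path.with_suffix(".hdr") if path.suffix != ".hdr" else path
    raw_path = hdr_path.with_suffix(".raw")
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found: {hdr_path}")
    if not raw_path.exists():
        raise FormatError(f"ENVI binary not found: {raw_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    def need(key: str) -> str:
        if key not in fields:
            raise FormatError(f"ENVI header missing required key {key!r}")
        return fields[key]

    samples = int(need("samples"))
    lines = int(need("lines"))
    bands = int(need("bands"))
    dcode = int(need("data type"))
    interleave = need("interleave").lower()
    if dcode not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dcode}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported ENVI interleave {interleave!r}")
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(_ENVI_DTYPES[dcode]).newbyteorder("<" if byte_order == 0 else ">")

    wav_field = need("wavelength")
    if not wav_field.startswith("{"):
        raise FormatError("ENVI wavelength field must be a { ... } list")
    wavelengths = np.array(
        [float(tok) for tok in wav_field.strip("{}").replace("\n", " ").split(",")
         if tok.strip()],
        dtype=np.float64,
    )
    if len(wavelengths) != bands:
        raise FormatError(
            f"ENVI header lists {len(wavelengths)} wavelengths for {bands} bands"
        )
    units = fields.get("wavelength units", "nanometers").strip().lower()
    if units.startswith("microm") or units in ("um", "micrometers"):
        logger.info("converting ENVI wavelengths from micrometers to nm")
        wavelengths = wavelengths * 1000.0

    raw = np.fromfile(raw_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"ENVI binary has {raw.size} values, expected {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bsq":        # (bands, lines, samples)
        arr = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":      # (lines, bands, samples)
        arr = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                          # bip: (lines, samples, bands)
        arr = raw.reshape(lines, samples, bands)
    arr = arr.astype(np.float64)
    if np.any(~np.isfinite(arr)) or arr.min() < 0:
        raise ValidationError(f"ENVI cube {raw_path} contains NaN or negative intensities")

    pixel_size = float(fields.get("pixel size um", "1.0"))
    grid = _grid_from_wavelengths(wavelengths)
    return HyperspectralCube(arr, grid, pixel_size, {"source": str(hdr_path)})


def _write_envi(cube: HyperspectralCube, path: Path) -> Path:
    hdr_path = path.with_suffix(".hdr")
    raw_path = path.with_suffix(".raw")
    h, w, b = cube.shape
    data = cube.intensities.astype("<f8")
    # BSQ: band-sequential
    data.transpose(2, 0, 1).tofile(raw_path)
    wav = ", ".join(f"{x:g}" for x in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "data type = 5\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nanometers\n"
        f"pixel size um = {cube.pixel_size_um!r}\n"
        "wavelength = { " + wav + " }\n"
    )
    hdr_path.write_text(hdr)
    return hdr_path


# ---------------------------------------------------------------------------
# Fixture dialect (bit-exact float32 JSON+binary pair)

def _read_fixture(path: Path) -> HyperspectralCube:
    json_path = path.with_suffix(".json")
    bin_path = path.with_suffix(".bin")
    if not json_path.exists():
        raise FormatError(f"fixture sidecar not found: {json_path}")
    meta = json.loads(json_path.read_text())
    for key in ("height", "width", "bands", "start_nm", "stop_nm", "step_nm",
                "pixel_size_um"):
        if key not in meta:
            raise FormatError(f"fixture sidecar missing key {key!r}")
    if "wavelengths" in meta:
        grid = _grid_from_wavelengths(np.asarray(meta["wavelengths"]))
    else:
        grid = make_grid(meta["start_nm"], meta["stop_nm"], meta["step_nm"])
    if grid.n_bands != meta["bands"]:
        raise FormatError(
            f"fixture declares {meta['bands']} bands but grid has {grid.n_bands}"
        )
    raw = np.fromfile(bin_path, dtype="<f4")
    expected = meta["height"] * meta["width"] * meta["bands"]
    if raw.size != expected:
        raise FormatError(f"fixture binary has {raw.size} values, expected {expected}")
    arr = raw.reshape(meta["height"], meta["width"], meta["bands"])
    if np.any(~np.isfinite(arr)) or arr.min() < 0:
        raise ValidationError(f"fixture cube {bin_path} contains NaN or negative intensities")
    return HyperspectralCube(
        arr, grid, float(meta["pixel_size_um"]), dict(meta.get("metadata", {}))
    )


def _write_fixture(cube: HyperspectralCube, path: Path) -> Path:
    json_path = path.with_suffix(".json")
    bin_path = path.with_suffix(".bin")
    h, w, b = cube.shape
    meta = {
        "height": h,
        "width": w,
        "bands": b,
        "start_nm": cube.grid.start_nm,
        "stop_nm": cube.grid.stop_nm,
        "step_nm": cube.grid.step_nm,
        "pixel_size_um": cube.pixel_size_um,
        "dtype": "float32",
        "metadata": cube.metadata,
    }
    json_path.write_text(json.dumps(meta, indent=1, default=str))
    cube.intensities.astype("<f4").tofile(bin_path)
    return json_path


def read_cube(path: str | Path, dialect: str = "fixture") -> HyperspectralCube:
    """Read a hyperspectral cube from disk.

    Parameters
    ----------
    path : path-like
        Stem or full path of the file pair.
    dialect : {"envi", "fixture"}
        On-disk format; see the module docstring.
    """
    path = Path(path)
    if dialect == "envi":
        return _read_envi(path)
    if dialect == "fixture":
        return _read_fixture(path)
    raise ValidationError(f"unknown dialect {dialect!r}; expected 'envi' or 'fixture'")


def write_cube(cube: HyperspectralCube, path: str | Path,
               dialect: str = "fixture") -> Path:
    """Write a cube so that :func:`read_cube` reproduces it.

    The fixture dialect stores float32 and is bit-exact for float32 data;
    the ENVI dialect stores float64 and is bit-exact always.
    Returns the header/sidecar path written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "envi":
        return _write_envi(cube, path)
    if dialect == "fixture":
        return _write_fixture(cube, path)
    raise ValidationError(f"unknown dialect {dialect!r}; expected 'envi' or 'fixture'")
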