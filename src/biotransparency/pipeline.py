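"""End-to-end orchestration: cubes in, trait tables out.

A run processes a list of cubes (each tagged with its individual and
species), segments the eggs, estimates the seawater background, computes
per-egg transmittance spectra and the two transparency statistics, and
aggregates up to individuals and species.  Everything downstream of the
cube list is deterministic, so re-running a config reproduces its CSVs
byte for byte, and aggregation is order-independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import segmentation as seg
from . import stats as st
from . import transmittance as tr
from .errors import ValidationError
from .spectral_io import read_cube
from .transmittance import TAU_QC_LIMIT

logger = logging.getLogger(__name__)

__all__ = ["CubeInput", "RunConfig", "PipelineResult", "run_pipeline",
           "load_config"]


@dataclass(frozen=True)
class CubeInput:
    """One measurement: a cube on disk plus its biological identity."""

    path: str
    individual_id: str
    species: str
    dialect: str = "fixture"
    pixel_size_um: float | None = None   # override the file's value
    manual_diameters_um: tuple[float, ...] = ()  # per-egg override, in reading order


@dataclass(frozen=True)
class RunConfig:
    inputs: tuple[CubeInput, ...]
    output_dir: str = "results"
    segmentation: seg.SegmentationParams = field(
        default_factory=seg.SegmentationParams)
    guard_margin_px: int = 10
    roi_fraction: float = 1.0
    mu_from_band_mean: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        ids = [(c.path, c.individual_id) for c in self.inputs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate (path, individual_id) pairs in inputs")


@dataclass
class PipelineResult:
    per_egg: pd.DataFrame
    per_individual: pd.DataFrame
    per_species: pd.DataFrame
    spectra: list[tr.TransmittanceSpectrum]
    qc: dict
    output_files: dict[str, Path] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    inputs = tuple(
        CubeInput(
            path=i["path"],
            individual_id=i["individual_id"],
            species=i["species"],
            dialect=i.get("dialect", "fixture"),
            pixel_size_um=i.get("pixel_size_um"),
            manual_diameters_um=tuple(i.get("manual_diameters_um", ())),
        )
        for i in raw["inputs"]
    )
    seg_params = seg.SegmentationParams(**raw.get("segmentation", {}))
    return RunConfig(
        inputs=inputs,
        output_dir=raw.get("output_dir", "results"),
        segmentation=seg_params,
        guard_margin_px=raw.get("guard_margin_px", 10),
        roi_fraction=raw.get("roi_fraction", 1.0),
        mu_from_band_mean=raw.get("mu_from_band_mean", False),
        seed=raw.get("seed", 0),
        log_level=raw.get("log_level", "INFO"),
    )


def _resolved_config_dict(config: RunConfig) -> dict:
    return {
        "inputs": [
            {
                "path": c.path,
                "individual_id": c.individual_id,
                "species": c.species,
                "dialect": c.dialect,
                "pixel_size_um": c.pixel_size_um,
                "manual_diameters_um": list(c.manual_diameters_um),
            }
            for c in config.inputs
        ],
        "output_dir": config.output_dir,
        "segmentation": {
            "reference_band": [config.segmentation.reference_band.low_nm,
                               config.segmentation.reference_band.high_nm],
            "threshold_mode": config.segmentation.threshold_mode,
            "relative_level": config.segmentation.relative_level,
            "min_area_px": config.segmentation.min_area_px,
            "min_circularity": config.segmentation.min_circularity,
        },
        "guard_margin_px": config.guard_margin_px,
        "roi_fraction": config.roi_fraction,
        "mu_from_band_mean": config.mu_from_band_mean,
        "seed": config.seed,
    }


def process_cube(cube, cube_input: CubeInput, config: RunConfig
                 ) -> tuple[list[st.EggStats], list[tr.TransmittanceSpectrum], dict]:
    """Segment one cube and compute per-egg statistics.

    Returns the egg stats, the spectra and a QC record (rejections,
    out-of-range tau flags, masked bands).
    """
    if cube_input.pixel_size_um is not None:
        cube.pixel_size_um = cube_input.pixel_size_um
    regions = seg.segment_eggs(cube, config.segmentation)
    qc = {"individual_id": cube_input.individual_id,
          "n_regions": len(regions), "tau_gt_limit_bands": 0,
          "mu_masked_bands": 0}
    if not regions:
        return [], [], qc
    bg = seg.background_mask(cube, regions, config.guard_margin_px)
    background = tr.estimate_background_spectrum(cube, bg)
    egg_stats: list[st.EggStats] = []
    spectra: list[tr.TransmittanceSpectrum] = []
    for i, region in enumerate(regions):
        spectrum = tr.egg_transmittance(cube, region, background,
                                        roi_fraction=config.roi_fraction)
        egg_id = f"{cube_input.individual_id}-egg{region.label}"
        spectrum = tr.TransmittanceSpectrum(spectrum.grid, spectrum.tau,
                                            egg_id=egg_id,
                                            n_pixels=spectrum.n_pixels)
        if i < len(cube_input.manual_diameters_um):
            diameter = cube_input.manual_diameters_um[i]
        else:
            diameter = region.equivalent_diameter_um
        stats = st.compute_egg_stats(
            spectrum, diameter,
            individual_id=cube_input.individual_id,
            species=cube_input.species,
            mu_from_band_mean=config.mu_from_band_mean,
        )
        qc["tau_gt_limit_bands"] += spectrum.qc_bands_above_unity
        qc["mu_masked_bands"] += int((~pd.notna(stats.mu_spectrum)).sum())
        egg_stats.append(stats)
        spectra.append(spectrum)
    return egg_stats, spectra, qc


def _aggregate(all_stats: list[st.EggStats]) -> tuple[pd.DataFrame, pd.DataFrame,
                                                      pd.DataFrame]:
    per_egg = pd.DataFrame(
        [
            {
                "egg_id": s.egg_id,
                "individual_id": s.individual_id,
                "species": s.species,
                "diameter_um": s.diameter_um,
                "bio_transparency_pct": s.bio_transparency_pct,
                "mu_visible_per_um": s.mu_visible_per_um,
            }
            for s in all_stats
        ],
        columns=["egg_id", "individual_id", "species", "diameter_um",
                 "bio_transparency_pct", "mu_visible_per_um"],
    ).sort_values(["individual_id", "egg_id"]).reset_index(drop=True)

    individuals: list[st.IndividualSummary] = []
    for ind_id in sorted({s.individual_id for s in all_stats}):
        group = [s for s in all_stats if s.individual_id == ind_id]
        individuals.append(st.aggregate_individual(group))
    per_individual = pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "species": i.species,
                "n_eggs": i.n_eggs,
                "mean_bt_pct": i.mean_bt_pct,
                "sd_bt_pct": i.sd_bt_pct,
                "mean_mu": i.mean_mu,
                "sd_mu": i.sd_mu,
                "single_egg_flag": i.single_egg,
            }
            for i in individuals
        ],
        columns=["individual_id", "species", "n_eggs", "mean_bt_pct",
                 "sd_bt_pct", "mean_mu", "sd_mu", "single_egg_flag"],
    )

    species_rows = []
    for sp in sorted({i.species for i in individuals}):
        group = [i for i in individuals if i.species == sp]
        summary = st.species_variance(group)
        species_rows.append(
            {
                "species": summary.species,
                "n_individuals": summary.n_individuals,
                "mean_bt_pct": float(pd.Series(summary.individual_means).mean()),
                "variance_bt": summary.variance_bt,
                "range_bt": summary.range_bt,
                "single_individual_flag": summary.n_individuals == 1,
            }
        )
    per_species = pd.DataFrame(
        species_rows,
        columns=["species", "n_individuals", "mean_bt_pct", "variance_bt",
                 "range_bt", "single_individual_flag"],
    )
    return per_egg, per_individual, per_species


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Process every input cube and aggregate to trait tables.

    Writes per-egg / per-individual / per-species CSVs, long-format
    spectra, a QC report and the resolved config into ``output_dir``.
    Zero eggs across all inputs is a warning, not an error.
    """
    all_stats: list[st.EggStats] = []
    all_spectra: list[tr.TransmittanceSpectrum] = []
    qc_records = []
    for cube_input in config.inputs:
        cube = read_cube(cube_input.path, cube_input.dialect)
        stats, spectra, qc = process_cube(cube, cube_input, config)
        all_stats.extend(stats)
        all_spectra.extend(spectra)
        qc_records.append(qc)

    per_egg, per_individual, per_species = _aggregate(all_stats)
    if per_egg.empty:
        logger.warning("no eggs found in any input cube; tables are empty")

    qc = {
        "n_cubes": len(config.inputs),
        "n_eggs": len(all_stats),
        "tau_qc_limit": TAU_QC_LIMIT,
        "per_cube": qc_records,
    }
    result = PipelineResult(per_egg, per_individual, per_species,
                            all_spectra, qc)
    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "per_egg": out / "per_egg.csv",
            "per_individual": out / "per_individual.csv",
            "per_species": out / "per_species.csv",
            "spectra": out / "spectra_long.csv",
            "qc": out / "qc_report.json",
            "config": out / "resolved_config.yaml",
        }
        per_egg.to_csv(files["per_egg"], index=False, float_format="%.10g")
        per_individual.to_csv(files["per_individual"], index=False,
                              float_format="%.10g")
        per_species.to_csv(files["per_species"], index=False,
                           float_format="%.10g")
        tr.spectra_to_long_csv(all_spectra, files["spectra"])
        files["qc"].write_text(json.dumps(qc, indent=1, default=str))
        files["config"].write_text(yaml.safe_dump(_resolved_config_dict(config),
                                                  sort_keys=True))
        result.output_files = files
    return result
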