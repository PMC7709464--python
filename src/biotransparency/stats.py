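"""Bio-transparency and attenuation-coefficient statistics.

Two complementary summaries of how see-through an egg is:

* **bio-transparency** -- 100 x the mean transmittance over the visible
  band 400-760 nm; a percentage at the whole-egg level.
* **attenuation coefficient** -- mu(lambda) = -ln(tau)/x with x the egg
  thickness (equivalent-circle diameter, um), i.e. the Beer-Lambert
  log-loss per unit path length.  It removes egg size from the
  comparison: a big egg can look opaque yet attenuate little per um.

Aggregation follows the measurement hierarchy egg -> individual ->
species.  Individuals are summarized by mean +/- sample SD; species by
the variance (population, n denominator) and the range of their
individual means -- both are reported because "spread across individuals"
admits either reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import BandRangeError, DegenerateSpectrumError, ValidationError
from .spectral_io import BandDefinition, VISIBLE_BAND
from .transmittance import TransmittanceSpectrum, band_mean

logger = logging.getLogger(__name__)

__all__ = [
    "EggStats",
    "IndividualSummary",
    "SpeciesSummary",
    "bio_transparency",
    "attenuation_spectrum",
    "visible_attenuation",
    "compute_egg_stats",
    "aggregate_individual",
    "species_variance",
]


@dataclass(frozen=True)
class EggStats:
    """Per-egg results: identity, size, and the two statistics."""

    egg_id: str
    individual_id: str
    species: str
    diameter_um: float
    bio_transparency_pct: float
    mu_visible_per_um: float
    mu_spectrum: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class IndividualSummary:
    individual_id: str
    species: str
    n_eggs: int
    mean_bt_pct: float
    sd_bt_pct: float
    mean_mu: float
    sd_mu: float
    single_egg: bool = False  # SD is 0 by convention when n = 1; flagged


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_individuals: int
    individual_means: tuple[float, ...]
    variance_bt: float  # population variance of individual means, %^2
    range_bt: float     # max - min of individual means, %


def bio_transparency(spectrum: TransmittanceSpectrum,
                     visible: BandDefinition = VISIBLE_BAND) -> float:
    """Bio-transparency in percent: 100 x mean tau over the visible band."""
    return 100.0 * band_mean(spectrum, visible)


def attenuation_spectrum(spectrum: TransmittanceSpectrum,
                         diameter_um: float) -> np.ndarray:
    """Per-band attenuation coefficient mu(lambda) = -ln(tau)/x in 1/um.

    Bands with tau >= 1 give mu <= 0 and are kept (QC downstream); bands
    with tau <= 0 have no defined log-loss and come back as NaN with a
    logged count.  A spectrum that is nonpositive everywhere is degenerate.
    """
    if not diameter_um > 0:
        raise ValidationError(f"diameter_um must be > 0, got {diameter_um}")
    tau = spectrum.tau
    if np.all(tau <= 0):
        raise DegenerateSpectrumError(
            f"egg {spectrum.egg_id or '?'}: tau nonpositive in every band"
        )
    mu = np.full_like(tau, np.nan, dtype=np.float64)
    ok = tau > 0
    mu[ok] = -np.log(tau[ok]) / diameter_um
    n_masked = int((~ok).sum())
    if n_masked:
        logger.warning("egg %s: %d band(s) with tau <= 0 masked in mu",
                       spectrum.egg_id or "?", n_masked)
    return mu


def visible_attenuation(mu_spectrum: np.ndarray,
                        grid,
                        visible: BandDefinition = VISIBLE_BAND) -> float:
    """Mean of mu(lambda) over the visible band, skipping masked bands."""
    sel = visible.selector(grid)
    if not sel.any():
        raise BandRangeError(
            f"band {visible.name} does not overlap the grid"
        )
    vals = np.asarray(mu_spectrum, dtype=np.float64)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DegenerateSpectrumError(
            "all visible bands are masked; no attenuation estimate possible"
        )
    return float(vals.mean())


def compute_egg_stats(spectrum: TransmittanceSpectrum, diameter_um: float,
                      individual_id: str = "", species: str = "",
                      visible: BandDefinition = VISIBLE_BAND,
                      mu_from_band_mean: bool = False) -> EggStats:
    """Bundle the two statistics for one egg.

    By default mu is computed per wavelength and then averaged over the
    visible band, which preserves the Beer-Lambert relation band-wise.
    ``mu_from_band_mean`` instead applies the log to the band-mean tau
    (the alternative reading of a "visible-range" coefficient), for
    comparison.
    """
    bt = bio_transparency(spectrum, visible)
    mu_spec = attenuation_spectrum(spectrum, diameter_um)
    if mu_from_band_mean:
        tau_bar = band_mean(spectrum, visible)
        if tau_bar <= 0:
            raise DegenerateSpectrumError("band-mean tau nonpositive")
        mu_vis = -float(np.log(tau_bar)) / diameter_um
    else:
        mu_vis = visible_attenuation(mu_spec, spectrum.grid, visible)
    return EggStats(
        egg_id=spectrum.egg_id,
        individual_id=individual_id,
        species=species,
        diameter_um=float(diameter_um),
        bio_transparency_pct=bt,
        mu_visible_per_um=mu_vis,
        mu_spectrum=mu_spec,
    )


def aggregate_individual(stats: list[EggStats]) -> IndividualSummary:
    """Mean and sample SD (n-1) of both statistics over one animal's eggs."""
    if not stats:
        raise ValidationError("need at least one egg to summarize an individual")
    ids = {s.individual_id for s in stats}
    if len(ids) != 1:
        raise ValidationError(f"mixed individual_ids in one aggregation: {sorted(ids)}")
    species = {s.species for s in stats}
    if len(species) != 1:
        raise ValidationError(f"mixed species for one individual: {sorted(species)}")
    bt = np.array([s.bio_transparency_pct for s in stats])
    mu = np.array([s.mu_visible_per_um for s in stats])
    n = len(stats)
    single = n == 1
    if single:
        logger.info("individual %s has a single egg; SD reported as 0",
                    stats[0].individual_id)
    return IndividualSummary(
        individual_id=stats[0].individual_id,
        species=stats[0].species,
        n_eggs=n,
        mean_bt_pct=float(bt.mean()),
        sd_bt_pct=0.0 if single else float(bt.std(ddof=1)),
        mean_mu=float(mu.mean()),
        sd_mu=0.0 if single else float(mu.std(ddof=1)),
        single_egg=single,
    )


def species_variance(summaries: list[IndividualSummary]) -> SpeciesSummary:
    """Across-individual spread of bio-transparency within one species.

    Reports both the population variance (n denominator) of the
    individual mean bio-transparencies and their range (max - min); a
    single-individual species gets 0 for both.
    """
    if not summaries:
        raise ValidationError("need at least one individual to summarize a species")
    species = {s.species for s in summaries}
    if len(species) != 1:
        raise ValidationError(f"mixed species in one aggregation: {sorted(species)}")
    means = np.array([s.mean_bt_pct for s in summaries])
    return SpeciesSummary(
        species=summaries[0].species,
        n_individuals=len(summaries),
        individual_means=tuple(float(m) for m in means),
        variance_bt=float(means.var(ddof=0)),
        range_bt=float(means.max() - means.min()),
    )
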