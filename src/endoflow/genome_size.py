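"""Absolute genome size estimation against an internal reference standard.

In a two-step propidium-iodide protocol the sample tissue is chopped and
stained together with a reference species of known DNA amount, so both
G0/G1 peaks sit on one histogram and

    2C_sample [pg] = 2C_standard [pg] * (sample peak mean / standard peak mean).

The default standard is *Solanum lycopersicum* 'Stupicke polni tyckove
rane' with 2C = 1.96 pg.  Conversions: 1 pg DNA = 978 Mbp; DNA per
chromosome = 2C / 2n.  Each plant is measured on three different days and
averaged; a stability flag marks plants whose between-day spread
(range/mean) reaches 1.5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gating
from .errors import DomainError
from .reference import STANDARD_2C_PG

__all__ = [
    "GsMeasurement",
    "SpeciesKaryotype",
    "PlantEstimate",
    "GenomeSizeEstimate",
    "PG_PER_MBP",
    "estimate_2c",
    "pg_to_mbp",
    "per_chromosome",
    "aggregate_plant",
    "species_summary",
    "genome_size_span",
    "measure_from_events",
]

#: 1 pg of DNA corresponds to 978 Mbp.
MBP_PER_PG = 978.0
PG_PER_MBP = 1.0 / MBP_PER_PG

#: Between-day variation threshold (range/mean, %) above which a plant's
#: replicate measurements are flagged unstable.
STABILITY_THRESHOLD_PERCENT = 1.5


@dataclass(frozen=True)
class GsMeasurement:
    """One two-peak measurement: sample and standard G0/G1 peak summaries."""

    sample_peak_mean: float
    standard_peak_mean: float
    sample_cv: float = 0.0
    standard_cv: float = 0.0
    n_nuclei: int = 0
    day: str = ""
    plant: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.sample_peak_mean <= 0 or self.standard_peak_mean <= 0:
            raise DomainError("peak means must be positive")
        if self.sample_cv < 0 or self.standard_cv < 0:
            raise DomainError("CVs must be non-negative")

    @property
    def ratio(self) -> float:
        return self.sample_peak_mean / self.standard_peak_mean


@dataclass(frozen=True)
class SpeciesKaryotype:
    """Somatic chromosome count for a species (e.g. 2n = 2x = 14)."""

    species: str
    chrom_2n: int
    ploidy: str = "2x"
    aneuploid: bool = False

    def __post_init__(self) -> None:
        if self.chrom_2n < 1:
            raise DomainError("2n must be >= 1")
        if self.chrom_2n % 2 and not self.aneuploid:
            raise DomainError(
                f"odd 2n = {self.chrom_2n} must be flagged aneuploid"
            )


@dataclass
class PlantEstimate:
    plant: str
    species: str
    c2_pg: float
    spread_percent: float
    unstable: bool
    measurements: list[GsMeasurement] = field(default_factory=list)


@dataclass
class GenomeSizeEstimate:
    """Species-level summary in the shape of a published genome-size table."""

    species: str
    n_plants: int
    c2_pg: float
    c2_sd: float
    c2_min: float
    c2_max: float
    ratio: float
    c1_pg: float
    c1_mbp: float
    per_chromosome_pg: float | None = None


def estimate_2c(m: GsMeasurement, standard_2c_pg: float = STANDARD_2C_PG) -> float:
    """2C DNA amount (pg) from peak means: standard_2C * sample/standard."""
    if standard_2c_pg <= 0:
        raise DomainError("standard 2C must be positive")
    return standard_2c_pg * m.ratio


def pg_to_mbp(pg: float) -> float:
    """Convert a DNA amount from pg to Mbp (1 pg = 978 Mbp)."""
    if pg < 0:
        raise DomainError("DNA amount cannot be negative")
    return MBP_PER_PG * pg


def per_chromosome(c2_pg: float, karyotype: SpeciesKaryotype) -> float:
    """Mean DNA content per chromosome: 2C / 2n."""
    return c2_pg / karyotype.chrom_2n


def aggregate_plant(
    measurements: list[GsMeasurement], standard_2c_pg: float = STANDARD_2C_PG
) -> PlantEstimate:
    """Average a plant's replicate measurements into one 2C value.

    The stability flag is raised when the between-day spread, measured as
    (max - min)/mean of the replicate 2C values, reaches 1.5 %.
    """
    if not measurements:
        raise DomainError("need at least one measurement")
    c2 = np.array([estimate_2c(m, standard_2c_pg) for m in measurements])
    mean = float(c2.mean())
    spread = 100.0 * float(c2.max() - c2.min()) / mean
    first = measurements[0]
    return PlantEstimate(
        plant=first.plant,
        species=first.species,
        c2_pg=mean,
        spread_percent=spread,
        unstable=spread >= STABILITY_THRESHOLD_PERCENT,
        measurements=list(measurements),
    )


def species_summary(
    plants: list[PlantEstimate],
    karyotype: SpeciesKaryotype | None = None,
    standard_2c_pg: float = STANDARD_2C_PG,
) -> GenomeSizeEstimate:
    """Mean +/- sample SD (and min-max) of per-plant 2C values for one species."""
    if not plants:
        raise DomainError("need at least one plant")
    species = plants[0].species
    c2 = np.array([p.c2_pg for p in plants])
    mean = float(c2.mean())
    sd = float(c2.std(ddof=1)) if len(c2) > 1 else 0.0
    c1 = mean / 2.0
    return GenomeSizeEstimate(
        species=species,
        n_plants=len(plants),
        c2_pg=mean,
        c2_sd=sd,
        c2_min=float(c2.min()),
        c2_max=float(c2.max()),
        ratio=mean / standard_2c_pg,
        c1_pg=c1,
        c1_mbp=pg_to_mbp(c1),
        per_chromosome_pg=(per_chromosome(mean, karyotype) if karyotype else None),
    )


def genome_size_span(species_means: list[float] | np.ndarray) -> float:
    """Relative span of species genome sizes, %: 100*(max - min)/min
    (the smallest genome represents 100 %)."""
    means = np.asarray(species_means, dtype=float)
    if means.size == 0 or np.any(means <= 0):
        raise DomainError("species means must be positive and non-empty")
    return 100.0 * float(means.max() - means.min()) / float(means.min())


def measure_from_events(
    sample: gating.EventSample,
    n_bins: int = 512,
    standard_is_lower: bool = True,
    **kwargs,
) -> GsMeasurement:
    """Extract a two-peak measurement from a combined sample+standard event
    cloud: detect the two most prominent peaks on a linear histogram and
    identify the standard as the lower (default) or upper one."""
    hist = gating.build_histogram(sample, n_bins=n_bins, scale="linear")
    peaks = gating.detect_peaks(hist, events=sample.intensities, **kwargs)
    if len(peaks.peaks) < 2:
        raise DomainError("expected a sample peak and a standard peak")
    top2 = sorted(peaks.peaks, key=lambda p: p.height, reverse=True)[:2]
    lo, hi = sorted(top2, key=lambda p: p.position)
    std, smp = (lo, hi) if standard_is_lower else (hi, lo)
    return GsMeasurement(
        sample_peak_mean=smp.position,
        standard_peak_mean=std.position,
        sample_cv=smp.cv_percent,
        standard_cv=std.cv_percent,
        n_nuclei=len(sample),
        species=sample.meta.species,
        plant=sample.meta.individual,
    )


def summary_table(estimates: list[GenomeSizeEstimate]) -> pd.DataFrame:
    """Tabulate species summaries in the published column layout."""
    return pd.DataFrame(
        {
            "species": [e.species for e in estimates],
            "n_plants": [e.n_plants for e in estimates],
            "c2_pg": [round(e.c2_pg, 3) for e in estimates],
            "c2_sd": [round(e.c2_sd, 3) for e in estimates],
            "c2_min": [round(e.c2_min, 3) for e in estimates],
            "c2_max": [round(e.c2_max, 3) for e in estimates],
            "ratio": [round(e.ratio, 3) for e in estimates],
            "c1_pg": [round(e.c1_pg, 3) for e in estimates],
            "c1_mbp": [round(e.c1_mbp) for e in estimates],
            "pg_per_chromosome": [
                None if e.per_chromosome_pg is None else round(e.per_chromosome_pg, 3)
                for e in estimates
            ],
        }
    )
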