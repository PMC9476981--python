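"""Seeded synthetic flow-cytometry data with the structure the analysis
assumes.

Two levels are generated:

* **event level** — per-nucleus fluorescence samples: Gaussian peaks at a
  2C anchor channel and its doublings (SD = CV * position, how instrument
  CVs are quoted), an exponential debris tail below the 2C peak, and, for
  genome-size runs, a second population at the internal-standard position.
* **study level** — ploidy-class count tables with the published study's
  design: species x organ cells with their published mean class
  proportions, between-individual variation as a Dirichlet draw on the
  simplex (concentration set once to roughly match the published
  between-individual SDs), several replicates per root, and >= 3000 nuclei
  per measurement drawn multinomially.

Every function takes an explicit ``numpy.random.Generator`` (or a seed via
the study design); a fixed seed reproduces output byte-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .errors import DomainError, PeakOverlapWarning
from .gating import EventSample, SampleMeta

__all__ = [
    "OrganTemplate",
    "StudyDesign",
    "draw_individual_proportions",
    "simulate_events",
    "simulate_counts",
    "simulate_gs_sample",
    "simulate_study",
    "simulate_gs_table",
    "default_study",
]

#: Instrument-like 2C anchor channel (gating is scale-invariant, the value
#: is arbitrary).
DEFAULT_ANCHOR = 200.0


@dataclass(frozen=True)
class OrganTemplate:
    """Generator parameters for one species x organ cell."""

    species: str
    organ: str
    proportions: tuple[float, ...]  # over C-levels 2..64, sums to 1
    n_individuals: int = 20
    concentration: float = 60.0  # Dirichlet spread knob; larger = tighter
    anchor: float = DEFAULT_ANCHOR
    cv_percent: float = 3.0
    debris_fraction: float = 0.02

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise DomainError("proportions must be >= 0 and sum to 1")
        if self.concentration <= 0:
            raise DomainError("concentration must be positive")
        if not 0 < self.cv_percent <= 10:
            raise DomainError("peak CV must be in (0, 10] percent")


@dataclass
class StudyDesign:
    templates: list[OrganTemplate]
    nuclei_per_sample: int = 3000
    root_replicates: int = 3
    seed: int = 0
    localities: tuple[str, ...] = ("LOC1", "LOC2", "LOC3", "LOC4")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def draw_individual_proportions(
    t: OrganTemplate, rng: np.random.Generator
) -> np.ndarray:
    """One individual's class proportions: Dirichlet centred on the template
    means with spread set by the concentration; classes with a zero template
    mean stay exactly zero."""
    p = np.asarray(t.proportions, dtype=float)
    out = np.zeros_like(p)
    nz = p > 0
    if nz.sum() == 1:
        out[nz] = 1.0
        return out
    out[nz] = rng.dirichlet(t.concentration * p[nz])
    return out


def _truncated_exponential(
    rng: np.random.Generator, scale: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Exact inverse-CDF draw from Exp(scale) truncated to (lo, hi)."""
    a = 1.0 - np.exp(-lo / scale)
    b = 1.0 - np.exp(-hi / scale)
    u = rng.uniform(a, b, size=n)
    return -scale * np.log1p(-u)


def simulate_events(
    proportions,
    anchor_position: float = DEFAULT_ANCHOR,
    cv_percent: float = 3.0,
    debris_fraction: float = 0.0,
    n: int = 3000,
    rng: np.random.Generator | None = None,
    meta: SampleMeta | None = None,
) -> EventSample:
    """Per-nucleus intensities for one measurement.

    Class membership is multinomial over ``proportions`` (C-levels 2C
    upward); intensities are Gaussian at anchor * 2**k with SD =
    cv * position; a ``debris_fraction`` of events comes from an
    exponential tail below the 2C gate.  All intensities are positive.
    """
    rng = rng or np.random.default_rng()
    p = np.asarray(proportions, dtype=float)
    if n < 1:
        raise DomainError("need n >= 1 events")
    p = p / p.sum()
    n_debris = rng.binomial(n, debris_fraction) if debris_fraction > 0 else 0
    n_signal = n - n_debris
    class_counts = rng.multinomial(n_signal, p)
    chunks = []
    for k, m in enumerate(class_counts):
        if m == 0:
            continue
        pos = anchor_position * 2.0**k
        x = rng.normal(pos, cv_percent / 100.0 * pos, size=m)
        x = np.abs(x)  # guard: intensities must stay positive
        x[x == 0] = pos * 1e-6
        chunks.append(x)
    if n_debris:
        hi = anchor_position * 2.0**-0.5 * 0.95  # stay below the 2C gate
        chunks.append(
            _truncated_exponential(
                rng, scale=anchor_position / 4.0,
                lo=anchor_position * 0.02, hi=hi, n=n_debris,
            )
        )
    intensities = rng.permutation(np.concatenate(chunks))
    return EventSample(intensities, meta=meta or SampleMeta(), scale_hint="log")


def simulate_counts(
    proportions, n: int, rng: np.random.Generator, meta: SampleMeta | None = None
):
    """Multinomial ploidy-class counts (the fast, count-level analogue of
    :func:`simulate_events` + gating)."""
    from .gating import PloidyCounts

    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    draws = rng.multinomial(n, p)
    counts = {
        level: float(m)
        for level, m in zip(reference.C_LEVELS, draws)
        if m > 0
    }
    return PloidyCounts(counts, meta=meta or SampleMeta())


def simulate_gs_sample(
    true_ratio: float,
    standard_position: float = DEFAULT_ANCHOR,
    cvs: tuple[float, float] = (3.0, 3.0),
    n: int = 5000,
    rng: np.random.Generator | None = None,
    meta: SampleMeta | None = None,
) -> EventSample:
    """Combined standard + sample event cloud for genome-size estimation.

    The standard population sits at ``standard_position`` and the sample at
    ``true_ratio`` times that.  A ratio within 5 % of a power of two of the
    standard (including 1) risks peak overlap and triggers a warning.
    """
    if true_ratio <= 0:
        raise DomainError("ratio must be positive")
    k = round(np.log2(true_ratio))
    if abs(true_ratio / 2.0**k - 1.0) < 0.05:
        warnings.warn(
            f"sample/standard ratio {true_ratio:.3f} is within 5 % of a "
            "doubling of the standard; peaks may overlap",
            PeakOverlapWarning,
            stacklevel=2,
        )
    rng = rng or np.random.default_rng()
    n_std = rng.binomial(n, 0.5)
    std_cv, smp_cv = cvs
    std = np.abs(rng.normal(standard_position,
                            std_cv / 100.0 * standard_position, n_std))
    pos = standard_position * true_ratio
    smp = np.abs(rng.normal(pos, smp_cv / 100.0 * pos, n - n_std))
    intensities = rng.permutation(np.concatenate([std, smp]))
    intensities[intensities == 0] = standard_position * 1e-6
    return EventSample(intensities, meta=meta or SampleMeta(),
                       scale_hint="linear")


def simulate_study(design: StudyDesign, events: bool = False):
    """Simulate the whole study as a ploidy-count table (one row per
    measurement, in the standard count-table dialect) and, optionally, the
    per-measurement event samples.

    Roots get ``design.root_replicates`` replicate measurements per
    individual; every other organ one.  Deterministic from ``design.seed``.
    """
    rng = design.rng()
    rows = []
    event_samples: list[EventSample] = []
    for t in design.templates:
        for i in range(t.n_individuals):
            plant = f"{t.species.replace(' ', '_').replace('.', '')}_{i + 1:02d}"
            locality = design.localities[i % len(design.localities)]
            p_ind = draw_individual_proportions(t, rng)
            n_reps = design.root_replicates if t.organ == "root" else 1
            for rep in range(1, n_reps + 1):
                meta = SampleMeta(
                    species=t.species, organ=t.organ, individual=plant,
                    replicate=rep, locality=locality,
                )
                if events:
                    sample = simulate_events(
                        p_ind, anchor_position=t.anchor,
                        cv_percent=t.cv_percent,
                        debris_fraction=t.debris_fraction,
                        n=design.nuclei_per_sample, rng=rng, meta=meta,
                    )
                    event_samples.append(sample)
                counts = simulate_counts(
                    p_ind, design.nuclei_per_sample, rng, meta=meta
                )
                row = {
                    "Species": t.species, "Locality": locality,
                    "Plant": plant, "Organ": t.organ, "ORG_rep": rep,
                }
                for level in reference.C_LEVELS:
                    row[f"{level}C"] = int(counts.counts.get(level, 0))
                rows.append(row)
    table = pd.DataFrame(rows)
    return (table, event_samples) if events else table


def simulate_gs_table(
    seed: int = 0,
    n_plants: int = 3,
    n_reps: int = 3,
    n_nuclei: int = 5000,
    cv_percent: float = 3.0,
    species_ratios: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Genome-size measurement table in the two-peak summary dialect:
    per-measurement nucleus counts, peak means and CVs for standard and
    sample, generated from event-level simulation and peak detection."""
    from .genome_size import measure_from_events

    if species_ratios is None:
        gs = reference.genome_size_table()
        species_ratios = dict(zip(gs.species, gs.ratio))
    rng = np.random.default_rng(seed)
    rows = []
    for species, ratio in species_ratios.items():
        for plant in range(1, n_plants + 1):
            for rep in range(1, n_reps + 1):
                sample = simulate_gs_sample(
                    ratio, cvs=(cv_percent, cv_percent), n=n_nuclei, rng=rng,
                    meta=SampleMeta(species=species, individual=str(plant)),
                )
                m = measure_from_events(sample)
                rows.append({
                    "Species": species,
                    "Plant_repetition": f"{plant}_{rep}",
                    "Area_std": m.n_nuclei // 2,
                    "Mean_std": round(m.standard_peak_mean, 3),
                    "CV_std": round(m.standard_cv, 3),
                    "Area_sample": m.n_nuclei - m.n_nuclei // 2,
                    "Mean_sample": round(m.sample_peak_mean, 3),
                    "CV_sample": round(m.sample_cv, 3),
                })
    return pd.DataFrame(rows)


def default_study(
    seed: int = 0,
    n_individuals: int | None = None,
    nuclei_per_sample: int = 3000,
    root_replicates: int = 3,
) -> StudyDesign:
    """The published study design as generator templates: every species x
    organ cell with its published mean class proportions and N (override
    ``n_individuals`` for a smaller fixture)."""
    templates = []
    tab = reference.class_proportion_table()
    for _, row in tab.iterrows():
        p = np.array([row[f"{c}C"] for c in reference.C_LEVELS], dtype=float)
        templates.append(
            OrganTemplate(
                species=row.species, organ=row.organ,
                proportions=tuple(p / p.sum()),
                n_individuals=(
                    int(row.n_plants) if n_individuals is None else n_individuals
                ),
            )
        )
    return StudyDesign(
        templates=templates,
        nuclei_per_sample=nuclei_per_sample,
        root_replicates=root_replicates,
        seed=seed,
    )
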