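"""End-to-end analysis stages over the library, shared by the CLI, the
numbered analysis drivers and the tests.

Stages: ``simulate`` (write a synthetic fixture study), ``gate`` (event
files -> ploidy-count table, excluding QC failures with a logged reason),
``genomesize`` (two-peak measurement table -> species genome-size summary),
``endopoly`` (ploidy-count table + genome sizes -> per-individual profiles,
per-cell summaries, between-group comparisons, dispersion CVs, PCA and the
standardized genome-size vs endopolyploidy trend).  Every stage is
deterministic given its inputs and the seed; each run can write its
resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, genome_size, groupstats, indices, io, reference, simulate
from .errors import EmptyInputError

log = logging.getLogger("endoflow")

__all__ = ["RunConfig", "run_simulate", "run_gate", "run_genomesize", "run_endopoly"]

NON_LEAF_ORGANS = ("root", "stem", "calyx", "corolla")


@dataclass
class RunConfig:
    standard_2c_pg: float = reference.STANDARD_2C_PG
    n_bins: int = 1024
    min_prominence_fraction: float = 0.02
    smoothing_window: int = 7
    tolerance_fraction: float = 0.10
    min_nuclei_genome_size: int = 5000
    min_nuclei_endopolyploidy: int = 3000
    max_cv_percent: float = 5.0
    alpha: float = 0.05
    seed: int = 0
    outdir: Path = field(default_factory=lambda: Path("results"))

    def write(self, outdir: Path | None = None) -> Path:
        """Write the resolved configuration next to the stage outputs."""
        outdir = Path(outdir or self.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "run_config.json"
        payload = dataclasses.asdict(self)
        payload["outdir"] = str(payload["outdir"])
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def run_simulate(
    config: RunConfig,
    n_individuals: int | None = 5,
    n_event_files: int = 3,
) -> dict[str, Path]:
    """Materialize a deterministic fixture study: a ploidy-count table, a
    genome-size measurement table and a few event-level files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = simulate.default_study(
        seed=config.seed,
        n_individuals=n_individuals,
        nuclei_per_sample=config.min_nuclei_endopolyploidy,
    )
    table = simulate.simulate_study(design)
    ploidy_path = outdir / "ploidy_counts.tsv"
    io.write_ploidy_table(table, ploidy_path)
    gs = simulate.simulate_gs_table(seed=config.seed,
                                    n_nuclei=config.min_nuclei_genome_size)
    gs_path = outdir / "genome_size_measurements.tsv"
    io.write_gs_table(gs, gs_path)

    events_dir = outdir / "events"
    events_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)
    for i, t in enumerate(design.templates[:n_event_files]):
        p = simulate.draw_individual_proportions(t, rng)
        # collect headroom over the QC floor so debris exclusion cannot
        # push a clean sample under the minimum-nuclei rule
        sample = simulate.simulate_events(
            p, anchor_position=t.anchor, cv_percent=t.cv_percent,
            debris_fraction=t.debris_fraction,
            n=int(1.2 * config.min_nuclei_endopolyploidy), rng=rng,
            meta=gating.SampleMeta(species=t.species, organ=t.organ,
                                   individual=f"sim_{i + 1}"),
        )
        io.write_event_table(
            sample, events_dir / f"events_{i + 1:02d}.tsv"
        )
    config.write(outdir)
    log.info("simulate: %d count rows, %d event files -> %s",
             len(table), min(n_event_files, len(design.templates)), outdir)
    return {"ploidy": ploidy_path, "genome_size": gs_path, "events": events_dir}


def run_gate(events_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    """Gate every event file in a directory into a ploidy-count table.

    Samples failing QC are excluded from the table with a logged reason,
    never silently dropped.
    """
    events_dir = Path(events_dir)
    paths = sorted(events_dir.glob("*.tsv"))
    if not paths:
        raise EmptyInputError(f"no event tables found in {events_dir}")
    rows = []
    excluded: list[tuple[str, str]] = []
    for path in paths:
        sample = io.read_event_table(path)
        counts, peaks = gating.gate_sample(
            sample,
            n_bins=config.n_bins,
            min_prominence_fraction=config.min_prominence_fraction,
            smoothing_window=config.smoothing_window,
            tolerance_fraction=config.tolerance_fraction,
        )
        report = gating.qc_check(
            counts, peaks, mode="endopolyploidy",
            min_nuclei=config.min_nuclei_endopolyploidy,
            max_cv_percent=config.max_cv_percent,
        )
        if not report.passed:
            excluded.append((path.name, "; ".join(report.violations)))
            continue
        row = {
            "Species": counts.meta.species, "Locality": counts.meta.locality,
            "Plant": counts.meta.individual, "Organ": counts.meta.organ,
            "ORG_rep": counts.meta.replicate,
        }
        for level in reference.C_LEVELS:
            row[f"{level}C"] = int(counts.counts.get(level, 0))
        rows.append(row)
    for name, reason in excluded:
        log.warning("gate: excluded %s (%s)", name, reason)
    log.info("gate: %d/%d samples retained", len(rows), len(paths))
    return pd.DataFrame(rows, columns=io.PLOIDY_COLUMNS)


def run_genomesize(
    gs_table: pd.DataFrame, config: RunConfig, karyotypes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per-species genome-size summary from a two-peak measurement table."""
    measurements = io.gs_table_to_measurements(gs_table)
    by_species_plant: dict[tuple[str, str], list] = {}
    for m in measurements:
        by_species_plant.setdefault((m.species, m.plant), []).append(m)
    plants_by_species: dict[str, list] = {}
    for (species, _plant), ms in sorted(by_species_plant.items()):
        est = genome_size.aggregate_plant(ms, config.standard_2c_pg)
        if est.unstable:
            log.warning(
                "genomesize: %s plant %s between-day spread %.2f %% >= 1.5 %%",
                species, est.plant, est.spread_percent,
            )
        plants_by_species.setdefault(species, []).append(est)
    estimates = []
    for species, plants in sorted(plants_by_species.items()):
        kt = None
        if karyotypes and species in karyotypes:
            kt = genome_size.SpeciesKaryotype(species, karyotypes[species])
        estimates.append(
            genome_size.species_summary(plants, kt, config.standard_2c_pg)
        )
    log.info("genomesize: %d measurements -> %d species", len(measurements),
             len(estimates))
    return genome_size.summary_table(estimates)


def _individual_profiles(
    table: pd.DataFrame, genome_sizes: dict[str, float] | None
) -> pd.DataFrame:
    """Per-measurement profiles, replicate-averaged within each
    species x organ x individual (index averaging, the study convention)."""
    genome_sizes = genome_sizes or {}
    groups: dict[tuple[str, str, str], list] = {}
    for counts in io.ploidy_table_to_counts(table):
        c2 = genome_sizes.get(counts.meta.species)
        prof = indices.profile_from_counts(counts, c2_pg=c2)
        key = (counts.meta.species, counts.meta.organ, counts.meta.individual)
        groups.setdefault(key, []).append(prof)
    rows = []
    for (species, organ, individual), profs in sorted(groups.items()):
        avg = indices.average_individual(profs)
        rows.append({
            "species": species, "organ": organ, "individual": individual,
            "n_replicates": len(profs), "ei": avg.ei, "mcv": avg.mcv,
            "e4p": avg.e4p, "p4c": avg.p4c, "ecmax": avg.ecmax,
            "meandna": avg.meandna,
        })
    return pd.DataFrame(rows)


def _class_proportion_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Species x organ mean +/- SD class percentages plus the highest
    observed endocycle number (replicates averaged per individual first)."""
    work = table.copy()
    class_cols = [f"{c}C" for c in reference.C_LEVELS]
    totals = work[class_cols].sum(axis=1)
    for col in class_cols:
        work[col] = 100.0 * work[col] / totals
    per_ind = work.groupby(["Species", "Organ", "Plant"], sort=True)[
        class_cols
    ].mean()
    rows = []
    for (species, organ), grp in per_ind.groupby(["Species", "Organ"], sort=True):
        row = {"species": species, "organ": organ, "n_plants": len(grp)}
        for col in class_cols:
            row[col] = grp[col].mean()
            row[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
        nonzero = [c for c, col in zip(reference.C_LEVELS, class_cols)
                   if grp[col].mean() > 0]
        row["ecmax"] = int(np.log2(max(nonzero) / 2)) if nonzero else 0
        rows.append(row)
    return pd.DataFrame(rows)


def _param_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (species, organ), grp in profiles.groupby(["species", "organ"], sort=True):
        row = {"species": species, "organ": organ, "n_plants": len(grp)}
        for param in ("ei", "mcv", "e4p", "p4c", "meandna"):
            vals = grp[param].dropna().astype(float)
            row[param] = vals.mean() if len(vals) else np.nan
            row[f"{param}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _comparisons(profiles: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Between-species tests within each organ, and between-organ tests
    within each species, for every parameter with enough data."""
    rows = []
    specs = [("organ", "species"), ("species", "organ")]
    for within, across in specs:
        for level, grp in profiles.groupby(within, sort=True):
            for param in ("ei", "mcv", "e4p", "p4c", "meandna"):
                sub = grp.dropna(subset=[param])
                sizes = sub.groupby(across)[param].size()
                keep = sizes[sizes >= 3].index
                sub = sub[sub[across].isin(keep)]
                if sub[across].nunique() < 2:
                    continue
                if sub[param].nunique() == 1:
                    continue
                res = groupstats.compare_groups(
                    sub[param].to_numpy(float), sub[across].to_numpy(), alpha=alpha
                )
                rows.append({
                    "within": within, "level": level, "across": across,
                    "parameter": param, "method": res.method,
                    "statistic": res.statistic, "pvalue": res.pvalue,
                    "letters": ";".join(
                        f"{g}={res.letters[g]}" for g in res.groups
                    ),
                })
    return pd.DataFrame(rows)


def _dispersion(
    param_summary: pd.DataFrame, genome_sizes: dict[str, float] | None
) -> pd.DataFrame:
    rows = []
    for organ, grp in param_summary.groupby("organ", sort=True):
        if len(grp) < 2:
            continue
        for param in ("ei", "meandna"):
            vals = grp[param].dropna()
            if len(vals) >= 2:
                d = groupstats.cv_across_species(vals, parameter=param, organ=organ)
                rows.append({"parameter": d.parameter.upper(), "organ": organ,
                             "cv_percent": d.cv_percent, "n": d.n})
    if genome_sizes and len(genome_sizes) >= 2:
        d = groupstats.cv_across_species(list(genome_sizes.values()),
                                         parameter="GS", organ="all")
        rows.append({"parameter": "GS", "organ": "all",
                     "cv_percent": d.cv_percent, "n": d.n})
    return pd.DataFrame(rows)


def _ordination(profiles: pd.DataFrame, param: str) -> groupstats.OrdinationResult | None:
    """Centred PCA of individuals x non-leaf organs; individuals missing
    any of the four organs are dropped (the documented convention)."""
    sub = profiles[profiles.organ.isin(NON_LEAF_ORGANS)]
    wide = sub.pivot_table(index=["species", "individual"], columns="organ",
                           values=param)
    wide = wide.reindex(columns=list(NON_LEAF_ORGANS)).dropna()
    if len(wide) < 3:
        return None
    return groupstats.pca_centered(wide, parameter=param)


def _size_vs_endopolyploidy_trend(
    param_summary: pd.DataFrame, genome_sizes: dict[str, float]
) -> pd.DataFrame:
    """Per-organ Spearman correlation between standardized species EI means
    and standardized genome sizes (sign of the size-endopolyploidy trend)."""
    from scipy import stats as sps

    rows = []
    for organ, grp in param_summary.groupby("organ", sort=True):
        grp = grp[grp.species.isin(genome_sizes)]
        if len(grp) < 3 or organ == "leaf":
            continue
        ei_z = groupstats.standardize(grp.ei.to_numpy(float))
        gs_z = groupstats.standardize(
            np.array([genome_sizes[s] for s in grp.species])
        )
        rho = sps.spearmanr(ei_z, gs_z).statistic
        rows.append({"organ": organ, "spearman_ei_vs_gs": float(rho)})
    return pd.DataFrame(rows)


def run_endopoly(
    ploidy_table: pd.DataFrame,
    genome_sizes: dict[str, float] | None,
    config: RunConfig,
) -> dict[str, object]:
    """The full endopolyploidy analysis over a ploidy-count table.

    ``genome_sizes`` maps species to the species-level mean 2C (pg); a
    species without one gets meanDNA flagged missing (NaN), never zero.
    """
    profiles = _individual_profiles(ploidy_table, genome_sizes)
    class_summary = _class_proportion_summary(ploidy_table)
    param_summary = _param_summary(profiles)
    comparisons = _comparisons(profiles, config.alpha)
    dispersion = _dispersion(param_summary, genome_sizes)
    result: dict[str, object] = {
        "profiles": profiles,
        "class_summary": class_summary,
        "param_summary": param_summary,
        "comparisons": comparisons,
        "dispersion": dispersion,
        "pca_ei": _ordination(profiles, "ei"),
        "pca_meandna": _ordination(profiles, "meandna"),
    }
    if genome_sizes:
        result["trend"] = _size_vs_endopolyploidy_trend(param_summary, genome_sizes)
    log.info("endopoly: %d measurements -> %d individuals, %d cells",
             len(ploidy_table), len(profiles), len(param_summary))
    return result
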