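"""Published summary statistics for the four Central European *Pulmonaria*
species whose study design this package emulates.

Three tables are embedded:

``genome_size_table()``
    Species-level genome size summaries: somatic chromosome number (2n),
    number of plants measured, 2C DNA amount (pg, mean +/- SD, min-max),
    sample/standard fluorescence ratio against the *Solanum lycopersicum*
    internal standard (2C = 1.96 pg), derived 1C values in pg and Mbp, and
    DNA content per chromosome.

``class_proportion_table()``
    Per species x organ mean +/- SD percentages of nuclei in the 2C...64C
    ploidy classes, the number of plants (N) and the maximal endocycle
    number implied by the highest detected class.

``endopoly_param_table()``
    Per species x organ means +/- SD of the five endopolyploidy parameters
    (EI, MCV, E4P, >=4C %, meanDNA in pg).

These printed values serve two roles: they parameterize the synthetic-data
generator (the study conditions) and they are the inputs for the
internal-consistency recomputations (the linear C-level indices applied to
the mean proportions reproduce the published parameter means).
"""

from __future__ import annotations

import pandas as pd

#: Ploidy classes (C-levels) used throughout: 2C after zero endocycles,
#: doubling with each endocycle up to 64C (five endocycles).
C_LEVELS: tuple[int, ...] = (2, 4, 8, 16, 32, 64)

#: 2C DNA amount of the internal reference standard
#: (*Solanum lycopersicum* 'Stupicke polni tyckove rane'), in pg.
STANDARD_2C_PG: float = 1.96

SPECIES: tuple[str, ...] = ("P. mollis", "P. murinii", "P. obscura", "P. officinalis")
ORGANS: tuple[str, ...] = ("root", "stem", "leaf", "calyx", "corolla")

_GS_ROWS = [
    # species, 2n, n_plants, 2C mean, sd, min, max, ratio mean, sd, 1C pg, 1C Mbp, pg/chromosome
    ("P. mollis", 18, 3, 3.176, 0.006, 3.171, 3.183, 1.620, 0.003, 1.588, 1553, 0.176),
    ("P. murinii", 14, 3, 2.311, 0.040, 2.269, 2.347, 1.179, 0.020, 1.156, 1130, 0.165),
    ("P. obscura", 14, 3, 2.687, 0.022, 2.673, 2.712, 1.371, 0.011, 1.343, 1314, 0.192),
    ("P. officinalis", 16, 3, 2.963, 0.018, 2.943, 2.978, 1.511, 0.009, 1.481, 1449, 0.185),
]

_GS_COLS = [
    "species", "chrom_2n", "n_plants", "c2_pg", "c2_sd", "c2_min", "c2_max",
    "ratio", "ratio_sd", "c1_pg", "c1_mbp", "pg_per_chromosome",
]

# species, organ, N, mean % per class 2C..64C, SD % per class, ECmax
_PROP_ROWS = [
    ("P. mollis", "root", 20, (35.88, 56.39, 7.73, 0.0, 0.0, 0.0), (7.00, 6.07, 2.90, 0.0, 0.0, 0.0), 2),
    ("P. mollis", "stem", 19, (40.77, 34.65, 21.88, 2.68, 0.02, 0.0), (6.37, 4.29, 3.12, 3.28, 0.07, 0.0), 4),
    ("P. mollis", "leaf", 3, (65.91, 27.25, 6.84, 0.0, 0.0, 0.0), (2.31, 2.07, 2.41, 0.0, 0.0, 0.0), 2),
    ("P. mollis", "calyx", 20, (79.54, 19.88, 0.58, 0.0, 0.0, 0.0), (10.58, 10.64, 0.87, 0.0, 0.0, 0.0), 2),
    ("P. mollis", "corolla", 20, (84.33, 15.07, 0.59, 0.0, 0.0, 0.0), (8.97, 8.06, 1.20, 0.0, 0.0, 0.0), 2),
    ("P. murinii", "root", 19, (15.74, 53.77, 28.91, 1.56, 0.02, 0.0), (4.15, 5.80, 6.30, 2.08, 0.09, 0.0), 4),
    ("P. murinii", "stem", 20, (24.05, 40.55, 19.77, 12.58, 3.02, 0.03), (4.60, 3.82, 4.00, 3.61, 3.50, 0.12), 5),
    ("P. murinii", "calyx", 20, (52.55, 44.50, 2.89, 0.05, 0.0, 0.0), (16.00, 14.45, 1.87, 0.17, 0.0, 0.0), 3),
    ("P. murinii", "corolla", 20, (57.87, 39.25, 2.88, 0.0, 0.0, 0.0), (9.08, 8.00, 1.47, 0.0, 0.0, 0.0), 2),
    ("P. obscura", "root", 25, (18.25, 45.56, 31.91, 4.27, 0.0, 0.0), (6.26, 7.21, 7.73, 3.74, 0.0, 0.0), 3),
    ("P. obscura", "stem", 25, (20.35, 41.46, 20.26, 15.25, 2.65, 0.04), (4.69, 4.48, 4.89, 6.71, 4.26, 0.20), 5),
    ("P. obscura", "leaf", 22, (55.70, 35.37, 8.83, 0.10, 0.0, 0.0), (8.71, 6.58, 7.48, 0.46, 0.0, 0.0), 3),
    ("P. obscura", "calyx", 25, (45.51, 50.74, 3.66, 0.09, 0.0, 0.0), (12.17, 11.51, 1.10, 0.22, 0.0, 0.0), 3),
    ("P. obscura", "corolla", 25, (56.17, 41.61, 2.13, 0.10, 0.0, 0.0), (10.22, 9.46, 1.00, 0.24, 0.0, 0.0), 3),
    ("P. officinalis", "root", 20, (31.95, 48.25, 19.51, 0.29, 0.0, 0.0), (9.49, 7.26, 8.02, 0.51, 0.0, 0.0), 3),
    ("P. officinalis", "stem", 20, (29.16, 37.95, 18.99, 12.89, 1.01, 0.0), (5.20, 3.31, 3.26, 5.07, 1.51, 0.0), 4),
    ("P. officinalis", "calyx", 20, (80.96, 18.17, 0.87, 0.0, 0.0, 0.0), (5.98, 5.59, 0.86, 0.0, 0.0, 0.0), 2),
    ("P. officinalis", "corolla", 20, (80.08, 19.24, 0.69, 0.0, 0.0, 0.0), (5.12, 4.71, 0.62, 0.0, 0.0, 0.0), 2),
]

# species, organ, N, (EI, MCV, E4P, >=4C %, meanDNA pg) means then SDs
_PARAM_ROWS = [
    ("P. mollis", "root", 20, (0.72, 3.59, 4.47, 64.12, 5.70), (0.09, 0.22, 0.16, 7.00, 0.35)),
    ("P. mollis", "stem", 19, (0.87, 4.39, 6.00, 59.23, 6.97), (0.13, 0.54, 0.57, 6.37, 0.85)),
    ("P. mollis", "leaf", 3, (0.41, 2.96, 4.80, 34.09, 4.69), (0.04, 0.13, 0.24, 2.31, 0.21)),
    ("P. mollis", "calyx", 20, (0.21, 2.43, 4.14, 20.46, 3.86), (0.11, 0.21, 0.22, 10.58, 0.34)),
    ("P. mollis", "corolla", 20, (0.16, 2.34, 4.09, 15.67, 3.71), (0.10, 0.22, 0.16, 8.97, 0.35)),
    ("P. murinii", "root", 19, (1.16, 5.03, 5.59, 84.26, 5.82), (0.12, 0.50, 0.49, 4.15, 0.58)),
    ("P. murinii", "stem", 20, (1.30, 6.68, 8.13, 75.95, 7.72), (0.14, 1.04, 1.14, 4.60, 1.20)),
    ("P. murinii", "calyx", 20, (0.50, 3.07, 4.24, 47.45, 3.55), (0.18, 0.39, 0.11, 16.00, 0.45)),
    ("P. murinii", "corolla", 20, (0.45, 2.96, 4.26, 42.13, 3.42), (0.10, 0.23, 0.11, 9.08, 0.27)),
    ("P. obscura", "root", 25, (1.22, 5.42, 6.17, 81.75, 7.28), (0.17, 0.71, 0.73, 6.26, 0.96)),
    ("P. obscura", "stem", 25, (1.39, 7.00, 8.22, 79.65, 9.40), (0.21, 1.56, 1.67, 4.69, 2.10)),
    ("P. obscura", "leaf", 22, (0.53, 3.25, 4.76, 44.30, 4.37), (0.15, 0.45, 0.63, 8.71, 0.60)),
    ("P. obscura", "calyx", 25, (0.58, 3.25, 4.29, 54.49, 4.36), (0.13, 0.27, 0.08, 12.17, 0.36)),
    ("P. obscura", "corolla", 25, (0.46, 2.97, 4.22, 43.83, 3.99), (0.11, 0.24, 0.10, 10.22, 0.32)),
    ("P. officinalis", "root", 20, (0.88, 4.18, 5.16, 68.05, 6.18), (0.16, 0.49, 0.43, 9.49, 0.73)),
    ("P. officinalis", "stem", 20, (1.19, 6.01, 7.61, 70.84, 8.89), (0.17, 0.92, 1.05, 5.20, 1.36)),
    ("P. officinalis", "calyx", 20, (0.20, 2.42, 4.17, 19.04, 3.58), (0.06, 0.14, 0.16, 5.98, 0.21)),
    ("P. officinalis", "corolla", 20, (0.21, 2.43, 4.13, 19.92, 3.59), (0.06, 0.12, 0.11, 5.12, 0.18)),
]

_PARAM_NAMES = ("ei", "mcv", "e4p", "p4c", "meandna")


def genome_size_table() -> pd.DataFrame:
    """Species-level genome size summary (one row per species)."""
    return pd.DataFrame(_GS_ROWS, columns=_GS_COLS)


def class_proportion_table() -> pd.DataFrame:
    """Mean +/- SD percentage of nuclei per ploidy class, per species x organ."""
    rows = []
    for species, organ, n, means, sds, ecmax in _PROP_ROWS:
        row = {"species": species, "organ": organ, "n_plants": n, "ecmax": ecmax}
        for c, m, s in zip(C_LEVELS, means, sds):
            row[f"{c}C"] = m
            row[f"{c}C_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def endopoly_param_table() -> pd.DataFrame:
    """Mean +/- SD of EI, MCV, E4P, >=4C and meanDNA per species x organ."""
    rows = []
    for species, organ, n, means, sds in _PARAM_ROWS:
        row = {"species": species, "organ": organ, "n_plants": n}
        for name, m, s in zip(_PARAM_NAMES, means, sds):
            row[name] = m
            row[f"{name}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def mean_proportions(species: str, organ: str) -> dict[int, float]:
    """Mean ploidy-class proportions (fractions summing to ~1) for one
    species x organ cell of the published design."""
    tab = class_proportion_table()
    row = tab[(tab.species == species) & (tab.organ == organ)]
    if row.empty:
        raise KeyError(f"no published cell for {species!r} / {organ!r}")
    r = row.iloc[0]
    return {c: float(r[f"{c}C"]) / 100.0 for c in C_LEVELS}
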