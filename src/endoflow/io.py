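"""Plain-text table input/output.

Three dialects, all delimiter-separated text (default tab):

* **event tables** — one intensity column plus optional metadata columns
  (``species``, ``organ``, ``individual``, ``replicate``), one row per
  nucleus.
* **ploidy-count tables** — one row per measurement with columns
  ``Species, Locality, Plant, Organ, ORG_rep, 2C, 4C, 8C, 16C, 32C, 64C``.
* **genome-size tables** — one row per two-peak measurement with columns
  ``Species, Plant_repetition, Area_std, Mean_std, CV_std, Area_sample,
  Mean_sample, CV_sample`` (the standard is the internal reference).

Reading an event table drops non-numeric or non-positive intensity rows
and emits a single warning carrying the rejected-row count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import EmptyInputError, FormatError
from .gating import EventSample, PloidyCounts, SampleMeta
from .genome_size import GsMeasurement
from .reference import C_LEVELS

__all__ = [
    "EventDialect",
    "read_event_table",
    "write_event_table",
    "read_ploidy_table",
    "write_ploidy_table",
    "ploidy_table_to_counts",
    "read_gs_table",
    "gs_table_to_measurements",
    "write_gs_table",
]

PLOIDY_COLUMNS = ["Species", "Locality", "Plant", "Organ", "ORG_rep"] + [
    f"{c}C" for c in C_LEVELS
]

GS_COLUMNS = [
    "Species", "Plant_repetition",
    "Area_std", "Mean_std", "CV_std",
    "Area_sample", "Mean_sample", "CV_sample",
]


@dataclass(frozen=True)
class EventDialect:
    delimiter: str = "\t"
    intensity_column: str = "intensity"


def read_event_table(
    path: str | Path, dialect: EventDialect = EventDialect()
) -> EventSample:
    """Read per-nucleus events; metadata columns are picked up when present."""
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.intensity_column not in df.columns:
        raise FormatError(
            f"{path}: missing intensity column {dialect.intensity_column!r}"
        )
    raw = pd.to_numeric(df[dialect.intensity_column], errors="coerce")
    ok = raw.notna() & (raw > 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} non-numeric/non-positive "
            "intensity rows",
            stacklevel=2,
        )
    if ok.sum() == 0:
        raise EmptyInputError(f"{path}: no usable event rows")
    first = df.loc[ok].iloc[0]
    meta = SampleMeta(
        species=str(first.get("species", "")),
        organ=str(first.get("organ", "")),
        individual=str(first.get("individual", "")),
        replicate=int(first.get("replicate", 1)),
    )
    return EventSample(raw[ok].to_numpy(float), meta=meta)


def write_event_table(
    sample: EventSample, path: str | Path, dialect: EventDialect = EventDialect()
) -> None:
    df = pd.DataFrame({dialect.intensity_column: sample.intensities})
    df["species"] = sample.meta.species
    df["organ"] = sample.meta.organ
    df["individual"] = sample.meta.individual
    df["replicate"] = sample.meta.replicate
    df.to_csv(path, sep=dialect.delimiter, index=False)


def read_ploidy_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in PLOIDY_COLUMNS[:5] if c not in df.columns]
    if missing or not any(f"{c}C" in df.columns for c in C_LEVELS):
        raise FormatError(f"{path}: not a ploidy-count table (missing {missing})")
    for c in C_LEVELS:  # absent high classes read back as zero
        if f"{c}C" not in df.columns:
            df[f"{c}C"] = 0
    return df[PLOIDY_COLUMNS].fillna(0)


def write_ploidy_table(
    table: pd.DataFrame, path: str | Path, delimiter: str = "\t"
) -> None:
    table.to_csv(path, sep=delimiter, index=False)


def ploidy_table_to_counts(table: pd.DataFrame) -> list[PloidyCounts]:
    """One :class:`PloidyCounts` per table row, metadata attached."""
    out = []
    for _, row in table.iterrows():
        counts = {
            c: float(row[f"{c}C"]) for c in C_LEVELS if float(row[f"{c}C"]) > 0
        }
        meta = SampleMeta(
            species=str(row["Species"]), organ=str(row["Organ"]),
            individual=str(row["Plant"]), replicate=int(row["ORG_rep"]),
            locality=str(row.get("Locality", "")),
        )
        out.append(PloidyCounts(counts, meta=meta))
    return out


def read_gs_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in GS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing genome-size columns {missing}")
    return df


def gs_table_to_measurements(table: pd.DataFrame) -> list[GsMeasurement]:
    out = []
    for _, row in table.iterrows():
        plant, _, rep = str(row["Plant_repetition"]).partition("_")
        out.append(
            GsMeasurement(
                sample_peak_mean=float(row["Mean_sample"]),
                standard_peak_mean=float(row["Mean_std"]),
                sample_cv=float(row["CV_sample"]),
                standard_cv=float(row["CV_std"]),
                n_nuclei=int(row["Area_std"]) + int(row["Area_sample"]),
                day=rep,
                plant=plant,
                species=str(row["Species"]),
            )
        )
    return out


def write_gs_table(
    table: pd.DataFrame, path: str | Path, delimiter: str = "\t"
) -> None:
    table.to_csv(path, sep=delimiter, index=False)
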