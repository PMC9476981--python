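"""Endopolyploidy parameters computed from ploidy-class nucleus counts.

With n_k nuclei in class 2^k * 2C (k endocycles), N = sum n_k and
f_k = n_k / N:

==========  =====================================================  =========
parameter   definition                                             units
==========  =====================================================  =========
EI          sum k * f_k            (mean endocycles per nucleus)   cycles
MCV         sum 2^(k+1) * f_k      (mean C-value)                  C
E4P         sum_{k>=1} 2^(k+1) n_k / sum_{k>=1} n_k                C
>=4C        100 * sum_{k>=1} f_k                                   %
ECmax       max { k : n_k > 0 }                                    cycles
meanDNA     MCV * 2C[pg] / 2  (= MCV * 1C)                         pg
==========  =====================================================  =========

E4P is the mean C-value restricted to endopolyploid (>= 4C) nuclei; it is
undefined — reported as missing, never zero — when no such nucleus exists.
meanDNA ties the endopolyploidy level to the species genome size: it is the
expected DNA amount per nucleus in the tissue.  EI, MCV and >=4C are linear
in f, so the index of pooled counts equals the count-weighted mean of
per-replicate indices; the per-individual replicate-averaging convention
used for study tables instead averages the indices themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ContractViolation, DomainError
from .gating import PloidyCounts, SampleMeta

__all__ = [
    "EndopolyProfile",
    "endoreduplication_index",
    "mean_c_value",
    "e4p",
    "prop_4c",
    "ecmax",
    "mean_dna",
    "profile_from_counts",
    "average_individual",
    "pool_counts",
    "is_endopolyploid",
]

#: A tissue counts as endopolyploid when its endoreduplication index
#: exceeds this conventional threshold.
ENDOPOLYPLOID_EI_THRESHOLD = 0.1


@dataclass
class EndopolyProfile:
    """The endopolyploidy parameter suite for one measurement (or one
    individual after replicate averaging)."""

    ei: float
    mcv: float
    e4p: float | None
    p4c: float
    ecmax: int
    meandna: float | None = None
    meta: SampleMeta = field(default_factory=SampleMeta)
    n_nuclei: float = 0.0


def _fractions(c: PloidyCounts) -> dict[int, float]:
    if c.total <= 0:
        raise DomainError("empty ploidy counts")
    return c.proportions()


def _k(level: int) -> int:
    return int(round(math.log2(level / 2)))


def endoreduplication_index(c: PloidyCounts) -> float:
    """EI = sum k * f_k — the mean number of endocycles per nucleus."""
    return sum(_k(level) * f for level, f in _fractions(c).items())


def mean_c_value(c: PloidyCounts) -> float:
    """MCV = sum 2^(k+1) * f_k — the nucleus-weighted mean C-level."""
    return sum(level * f for level, f in _fractions(c).items())


def e4p(c: PloidyCounts) -> float | None:
    """Mean C-level among endopolyploid (>= 4C) nuclei; None when there are
    none (undefined, not zero)."""
    _fractions(c)  # validates non-empty
    endo = {level: n for level, n in c.counts.items() if level >= 4}
    n_endo = sum(endo.values())
    if n_endo <= 0:
        return None
    return sum(level * n for level, n in endo.items()) / n_endo


def prop_4c(c: PloidyCounts) -> float:
    """Percentage of nuclei at or above 4C — endocycle initiation estimate."""
    return 100.0 * sum(f for level, f in _fractions(c).items() if level >= 4)


def ecmax(c: PloidyCounts) -> int:
    """Largest number of endocycles with a non-empty class."""
    nonzero = [level for level, n in c.counts.items() if n > 0]
    if not nonzero:
        raise DomainError("empty ploidy counts")
    return _k(max(nonzero))


def mean_dna(mcv: float, c2_pg: float) -> float:
    """Tissue-specific mean DNA content: MCV * 2C / 2, in pg."""
    if mcv < 2:
        raise DomainError("MCV cannot fall below 2")
    if c2_pg <= 0:
        raise DomainError("genome size must be positive")
    return mcv * c2_pg / 2.0


def profile_from_counts(
    c: PloidyCounts, c2_pg: float | None = None
) -> EndopolyProfile:
    """Compute the full parameter suite for one measurement.

    ``c2_pg`` is the species-level mean 2C genome size; when missing,
    meanDNA is left as None (flagged missing, not zero).
    """
    mcv = mean_c_value(c)
    return EndopolyProfile(
        ei=endoreduplication_index(c),
        mcv=mcv,
        e4p=e4p(c),
        p4c=prop_4c(c),
        ecmax=ecmax(c),
        meandna=None if c2_pg is None else mean_dna(mcv, c2_pg),
        meta=c.meta,
        n_nuclei=c.total,
    )


def pool_counts(counts_list: list[PloidyCounts]) -> PloidyCounts:
    """Sum class counts across replicates (the linear alternative to
    index averaging; exact for EI, MCV and >=4C by linearity)."""
    if not counts_list:
        raise DomainError("nothing to pool")
    pooled: dict[int, float] = {}
    for c in counts_list:
        for level, n in c.counts.items():
            pooled[level] = pooled.get(level, 0.0) + n
    return PloidyCounts(pooled, meta=counts_list[0].meta,
                        debris=sum(c.debris for c in counts_list))


def average_individual(profiles: list[EndopolyProfile]) -> EndopolyProfile:
    """Average replicate profiles of one individual and organ.

    Each defined parameter is averaged arithmetically across replicates
    (E4P and meanDNA only over replicates where defined); ECmax is the
    maximum over replicates.
    """
    if not profiles:
        raise DomainError("need at least one profile")
    organs = {p.meta.organ for p in profiles}
    individuals = {p.meta.individual for p in profiles}
    if len(organs) > 1 or len(individuals) > 1:
        raise ContractViolation(
            f"replicates mix organs {organs} / individuals {individuals}"
        )
    n = len(profiles)
    e4ps = [p.e4p for p in profiles if p.e4p is not None]
    dnas = [p.meandna for p in profiles if p.meandna is not None]
    return EndopolyProfile(
        ei=sum(p.ei for p in profiles) / n,
        mcv=sum(p.mcv for p in profiles) / n,
        e4p=(sum(e4ps) / len(e4ps)) if e4ps else None,
        p4c=sum(p.p4c for p in profiles) / n,
        ecmax=max(p.ecmax for p in profiles),
        meandna=(sum(dnas) / len(dnas)) if dnas else None,
        meta=profiles[0].meta,
        n_nuclei=sum(p.n_nuclei for p in profiles),
    )


def is_endopolyploid(profile: EndopolyProfile) -> bool:
    """Conventional predicate: the tissue is endopolyploid when EI > 0.1."""
    return profile.ei > ENDOPOLYPLOID_EI_THRESHOLD
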