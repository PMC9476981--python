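"""DNA-content histogram gating: from per-nucleus fluorescence events to
nuclei counts per ploidy class.

A propidium-iodide flow-cytometry histogram of an endopolyploid plant organ
shows a dominant G0/G1 peak at the 2C DNA amount and further peaks at its
successive doublings (4C, 8C, ...), one per endocycle, riding on an
exponential debris background.  This module detects those peaks, anchors the
doubling series, draws class gates at the geometric midpoints between
adjacent peaks (symmetric under the doubling structure), and tallies events
per C-level class.  Everything is deterministic; randomness lives only in
:mod:`endoflow.simulate`.

The quality rules mirror routine cytometry practice for this kind of study:
at least 5000 nuclei and G0/G1 peak CVs <= 5 % for genome-size runs, at
least 3000 nuclei for endopolyploidy screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DomainError,
    InsufficientNucleiError,
    NoPeakError,
)

__all__ = [
    "SampleMeta",
    "EventSample",
    "Histogram",
    "Peak",
    "PeakSet",
    "PloidyCounts",
    "QCReport",
    "build_histogram",
    "detect_peaks",
    "assign_doubling_series",
    "extend_doubling_series",
    "gate_events",
    "gate_sample",
    "qc_check",
]

#: Outer gate half-width: the lowest/highest gates extend peak * 2**(+/-1/2),
#: i.e. half a doubling on the log2 axis, beyond the extreme assigned peaks.
OUTER_HALFWIDTH_LOG2 = 0.5

#: Peak measurement window half-width on the log2 axis (quarter doubling).
PEAK_WINDOW_LOG2 = 0.25


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one measurement: species, organ, individual, replicate."""

    species: str = ""
    organ: str = ""
    individual: str = ""
    replicate: int = 1
    locality: str = ""


@dataclass
class EventSample:
    """Per-nucleus relative fluorescence intensities plus metadata.

    ``scale_hint`` records how the instrument displayed the histogram
    (``"log"`` for endopolyploidy screens, ``"linear"`` for genome-size
    runs); gating works on either.
    """

    intensities: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)
    scale_hint: str = "log"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 1:
            raise DomainError("an event sample needs at least one intensity")
        if np.any(self.intensities <= 0):
            raise DomainError("fluorescence intensities must be positive")

    def __len__(self) -> int:
        return int(self.intensities.size)


@dataclass
class Histogram:
    """Binned events: ``len(counts) == len(bin_edges) - 1``."""

    bin_edges: np.ndarray
    counts: np.ndarray
    scale: str = "log"
    n_below_floor: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise DomainError("counts/bin_edges length mismatch")

    @property
    def centers(self) -> np.ndarray:
        """Bin centers in intensity units (geometric for log-scaled bins)."""
        if self.scale == "log":
            return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class Peak:
    position: float
    height: float
    cv_percent: float
    c_level: int | None = None  # 2 * 2**k for k >= 0, or None if unassigned


@dataclass
class PeakSet:
    peaks: list[Peak]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])

    def assigned(self) -> list[Peak]:
        return [p for p in self.peaks if p.c_level is not None]

    def unassigned(self) -> list[Peak]:
        return [p for p in self.peaks if p.c_level is None]


@dataclass
class PloidyCounts:
    """Nuclei counts per C-level class for one measurement.

    ``counts`` maps C-level (2, 4, 8, ...) to a non-negative count; counts
    may be fractional when constructed from published percentages.  Events
    outside all gates are tallied in ``debris`` and excluded from ``total``.
    """

    counts: dict[int, float]
    meta: SampleMeta = field(default_factory=SampleMeta)
    debris: float = 0.0

    def __post_init__(self) -> None:
        bad = [c for c in self.counts if c < 2 or 2 ** round(math.log2(c)) != c]
        if bad:
            raise DomainError(f"C-levels must be 2*2^k: {bad}")
        if any(v < 0 for v in self.counts.values()):
            raise DomainError("class counts must be non-negative")
        if self.total <= 0:
            raise DomainError("a ploidy-count record needs at least one nucleus")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def proportions(self) -> dict[int, float]:
        t = self.total
        return {c: v / t for c, v in self.counts.items()}

    @classmethod
    def from_proportions(
        cls, proportions: dict[int, float], meta: SampleMeta | None = None
    ) -> "PloidyCounts":
        """Build a (fractional) count record from class proportions or
        percentages; used when the input is a published summary row."""
        return cls({c: float(v) for c, v in proportions.items() if v > 0},
                   meta=meta or SampleMeta())


@dataclass
class QCReport:
    passed: bool
    violations: list[str]
    mode: str
    total_nuclei: float | None = None
    peak_cvs: tuple[float, ...] = ()


def build_histogram(
    sample: EventSample,
    n_bins: int = 1024,
    scale: str | None = None,
    floor: float | None = None,
) -> Histogram:
    """Bin events into ``n_bins`` channels, uniform in log(intensity) for the
    log scale (how endopolyploidy histograms are displayed) or in intensity
    for the linear scale.

    Events below ``floor`` (a debris cut, if given) are excluded from the
    histogram and reported in ``n_below_floor``.
    """
    if n_bins < 16:
        raise DomainError("n_bins must be >= 16")
    scale = scale or sample.scale_hint
    if scale not in ("log", "linear"):
        raise DomainError(f"unknown scale {scale!r}")
    x = sample.intensities
    n_below = 0
    if floor is not None:
        n_below = int(np.sum(x < floor))
        x = x[x >= floor]
        if x.size == 0:
            raise DomainError("floor removed every event")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # degenerate single-value sample: widen artificially
        lo, hi = lo * 0.9, hi * 1.1
    if scale == "log":
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return Histogram(edges, counts, scale=scale, n_below_floor=n_below)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    half = window // 2
    padded = np.pad(y.astype(float), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(y)]


def detect_peaks(
    hist: Histogram,
    min_prominence_fraction: float = 0.02,
    smoothing_window: int = 7,
    events: np.ndarray | None = None,
) -> PeakSet:
    """Locate fluorescence peaks on a smoothed histogram.

    Local maxima with prominence of at least ``min_prominence_fraction`` of
    the tallest smoothed bin are retained.  Each peak's position is then
    refined as the count-weighted mean intensity within a window of a
    quarter doubling either side (truncated at midpoints to neighbouring
    peaks), and its CV is the weighted standard deviation over the same
    window, from raw events when ``events`` is supplied, else from bins.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.sum() <= 0:
        raise NoPeakError("empty histogram")
    smooth = _moving_average(counts, smoothing_window)
    prominence = min_prominence_fraction * smooth.max()
    idx, _props = find_peaks(smooth, prominence=prominence)
    if idx.size == 0:
        raise NoPeakError("no peak above the prominence threshold")

    centers = hist.centers
    # merge maxima closer than a quarter doubling: true DNA-content peaks
    # sit a factor 2 apart, so anything nearer is binning noise on one peak
    merged: list[int] = []
    for i in idx:
        if merged and centers[i] / centers[merged[-1]] < 2.0**PEAK_WINDOW_LOG2:
            if smooth[i] > smooth[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    idx = np.asarray(merged)
    raw_positions = centers[idx]
    peaks: list[Peak] = []
    for j, i in enumerate(idx):
        pos0 = raw_positions[j]
        lo = pos0 * 2.0 ** (-PEAK_WINDOW_LOG2)
        hi = pos0 * 2.0 ** (PEAK_WINDOW_LOG2)
        # truncate at geometric midpoints to neighbouring detected peaks
        if j > 0:
            lo = max(lo, math.sqrt(raw_positions[j - 1] * pos0))
        if j < len(idx) - 1:
            hi = min(hi, math.sqrt(pos0 * raw_positions[j + 1]))
        if events is not None:
            win = events[(events >= lo) & (events < hi)]
            if win.size:
                mean = float(win.mean())
                sd = float(win.std(ddof=0))
                height = float(win.size)
            else:  # fall back to bins
                mean, sd, height = _window_moments(centers, counts, lo, hi)
        else:
            mean, sd, height = _window_moments(centers, counts, lo, hi)
        cv = 100.0 * sd / mean if mean > 0 else 0.0
        peaks.append(Peak(position=mean, height=height, cv_percent=cv))
    peaks.sort(key=lambda p: p.position)
    return PeakSet(peaks)


def _window_moments(
    centers: np.ndarray, counts: np.ndarray, lo: float, hi: float
) -> tuple[float, float, float]:
    mask = (centers >= lo) & (centers < hi)
    w = counts[mask]
    x = centers[mask]
    total = w.sum()
    if total <= 0:
        return 0.5 * (lo + hi), 0.0, 0.0
    mean = float(np.average(x, weights=w))
    var = float(np.average((x - mean) ** 2, weights=w))
    return mean, math.sqrt(var), float(total)


def _chain_matches(anchor: float, positions: np.ndarray, tol: float) -> int:
    """Number of *other* peaks lying within ``tol`` of anchor * 2**k, k>=1."""
    n = 0
    for p in positions:
        if p <= anchor:
            continue
        k = round(math.log2(p / anchor))
        if k >= 1 and abs(p / (anchor * 2.0**k) - 1.0) <= tol:
            n += 1
    return n


def assign_doubling_series(
    peakset: PeakSet, tolerance_fraction: float = 0.10
) -> PeakSet:
    """Anchor the 2C peak and assign C-levels along the doubling series.

    Anchor choice: the lowest peak whose doubling chain matches at least one
    other peak, when any peak has such a chain; otherwise the tallest peak.
    (The G0/G1 class dominates most organs, but 4C can dominate roots and
    stems, so chain consistency is preferred over height.)  Peaks within
    ``tolerance_fraction`` of anchor * 2**k get C-level 2 * 2**k; the rest
    are flagged unassigned, never dropped.
    """
    if not peakset.peaks:
        raise NoPeakError("cannot assign an empty peak set")
    positions = peakset.positions
    anchor_pos: float | None = None
    for p in sorted(positions):
        if _chain_matches(p, positions, tolerance_fraction) >= 1:
            anchor_pos = p
            break
    if anchor_pos is None:
        anchor_pos = max(peakset.peaks, key=lambda p: p.height).position

    # best-candidate assignment per k (keep the closest when two compete)
    best: dict[int, Peak] = {}
    out: list[Peak] = []
    for peak in sorted(peakset.peaks, key=lambda p: p.position):
        new = replace(peak, c_level=None)
        if peak.position >= anchor_pos * (1 - tolerance_fraction):
            k = max(0, round(math.log2(peak.position / anchor_pos)))
            rel = abs(peak.position / (anchor_pos * 2.0**k) - 1.0)
            if rel <= tolerance_fraction:
                prev = best.get(k)
                if prev is None or rel < abs(
                    prev.position / (anchor_pos * 2.0**k) - 1.0
                ):
                    if prev is not None:
                        prev.c_level = None
                    new.c_level = 2 * 2**k
                    best[k] = new
        out.append(new)
    return PeakSet(out)


def extend_doubling_series(
    peakset: PeakSet,
    events: np.ndarray,
    max_c_level: int = 64,
    min_events: int = 10,
) -> PeakSet:
    """Append gates for rare high-C classes the peak detector missed.

    Cytometry practice places regions at the *expected* doubling positions,
    so classes holding a fraction of a percent of nuclei are still counted
    even though they never rise above a histogram prominence threshold.
    Starting above the highest assigned peak, each successive doubling of
    the anchor that holds at least ``min_events`` events within a
    quarter-doubling window becomes an assigned peak; extension stops at
    the first empty doubling.
    """
    assigned = sorted(peakset.assigned(), key=lambda p: p.position)
    if not assigned:
        return peakset
    anchor = assigned[0].position
    top = assigned[-1]
    peaks = list(peakset.peaks)
    k = _k_of(top.c_level)
    while top.c_level * 2 <= max_c_level:
        k += 1
        pos = anchor * 2.0**k
        lo, hi = pos * 2.0**-PEAK_WINDOW_LOG2, pos * 2.0**PEAK_WINDOW_LOG2
        win = events[(events >= lo) & (events < hi)]
        if win.size < min_events:
            break
        mean = float(win.mean())
        cv = 100.0 * float(win.std(ddof=0)) / mean
        top = Peak(position=mean, height=float(win.size), cv_percent=cv,
                   c_level=2 * 2**k)
        peaks.append(top)
    peaks.sort(key=lambda p: p.position)
    return PeakSet(peaks)


def _k_of(c_level: int) -> int:
    return int(round(math.log2(c_level / 2)))


def gate_events(sample: EventSample, peakset: PeakSet) -> PloidyCounts:
    """Assign every event to a ploidy class.

    Gate boundaries are the geometric midpoints between adjacent assigned
    peaks (symmetric on the log2 axis); the outer boundaries extend half a
    doubling below the lowest and above the highest assigned peak.  Events
    outside all gates are counted as debris/aggregates and excluded from the
    class total.
    """
    assigned = sorted(peakset.assigned(), key=lambda p: p.position)
    if not assigned:
        raise NoPeakError("peak set carries no assigned C-levels")
    pos = np.array([p.position for p in assigned])
    levels = [p.c_level for p in assigned]
    inner = np.sqrt(pos[:-1] * pos[1:])
    lo = pos[0] * 2.0 ** (-OUTER_HALFWIDTH_LOG2)
    hi = pos[-1] * 2.0 ** (OUTER_HALFWIDTH_LOG2)
    boundaries = np.concatenate([[lo], inner, [hi]])
    x = sample.intensities
    bins = np.searchsorted(boundaries, x, side="right") - 1
    counts: dict[int, float] = {int(lv): 0.0 for lv in levels}
    inside = (bins >= 0) & (bins < len(levels))
    for b in bins[inside]:
        counts[int(levels[b])] += 1.0
    debris = float(x.size - inside.sum())
    if inside.sum() == 0:
        raise InsufficientNucleiError("no event fell inside any ploidy gate")
    return PloidyCounts(counts, meta=sample.meta, debris=debris)


def gate_sample(
    sample: EventSample,
    n_bins: int = 1024,
    min_prominence_fraction: float = 0.02,
    smoothing_window: int = 7,
    tolerance_fraction: float = 0.10,
    extend_series: bool = True,
) -> tuple[PloidyCounts, PeakSet]:
    """Full gating chain: histogram -> peaks -> doubling series (extended
    into rare high-C classes) -> counts."""
    hist = build_histogram(sample, n_bins=n_bins)
    peaks = detect_peaks(
        hist,
        min_prominence_fraction=min_prominence_fraction,
        smoothing_window=smoothing_window,
        events=sample.intensities,
    )
    assigned = assign_doubling_series(peaks, tolerance_fraction)
    if extend_series:
        assigned = extend_doubling_series(assigned, sample.intensities)
    return gate_events(sample, assigned), assigned


def qc_check(
    counts: PloidyCounts | None = None,
    peaks: PeakSet | None = None,
    mode: str = "endopolyploidy",
    min_nuclei: int | None = None,
    max_cv_percent: float = 5.0,
) -> QCReport:
    """Apply the measurement quality rules.

    Genome-size runs need >= 5000 nuclei; endopolyploidy screens >= 3000;
    in both modes every anchor-peak CV must not exceed ``max_cv_percent``
    (default 5 %).  Always returns a report; never raises.
    """
    if mode not in ("genome_size", "endopolyploidy"):
        raise DomainError(f"unknown QC mode {mode!r}")
    if min_nuclei is None:
        min_nuclei = 5000 if mode == "genome_size" else 3000
    violations: list[str] = []
    total = None
    if counts is not None:
        total = counts.total
        if total < min_nuclei:
            violations.append(
                f"only {total:.0f} nuclei collected; {mode} requires >= {min_nuclei}"
            )
    cvs: tuple[float, ...] = ()
    if peaks is not None:
        cvs = tuple(p.cv_percent for p in peaks.assigned() or peaks.peaks)
        for cv in cvs:
            if cv > max_cv_percent:
                violations.append(
                    f"peak CV {cv:.2f} % exceeds {max_cv_percent:.1f} %"
                )
    return QCReport(
        passed=not violations,
        violations=violations,
        mode=mode,
        total_nuclei=total,
        peak_cvs=cvs,
    )
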