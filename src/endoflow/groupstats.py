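"""Between-group comparison layer for endopolyploidy and genome-size data.

The workflow mirrors common practice in plant cytometry studies: check
ANOVA's assumptions (Shapiro-Wilk normality per group, Levene
homoscedasticity) and fall back to the nonparametric route when either
fails; run one-way ANOVA with Tukey's HSD, or Kruskal-Wallis with Dunn's
pairwise test under Benjamini-Hochberg adjustment; summarize pairwise
outcomes as a compact letter display (groups sharing a letter are not
significantly different at alpha).  Also provided: a Spearman correlation
matrix over parameter profiles, the across-species coefficient of
variation of organ-specific means, centred (not scaled) PCA, and z-score
standardization.

Dunn's test is implemented here directly (rank-sum z statistics with tie
correction); the adjustment reuses statsmodels' multipletests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "ComparisonResult",
    "DispersionSummary",
    "OrdinationResult",
    "gatekeep",
    "compare_groups",
    "dunn_test",
    "compact_letter_display",
    "spearman_matrix",
    "cv_across_species",
    "pca_centered",
    "standardize",
]


@dataclass
class ComparisonResult:
    method: str  # "anova_tukey" | "kruskal_dunn_bh"
    statistic: float
    pvalue: float
    groups: list[str]
    pairwise: dict[tuple[str, str], float]  # adjusted p per unordered pair
    letters: dict[str, str]
    alpha: float = 0.05


@dataclass
class DispersionSummary:
    parameter: str
    organ: str
    cv_percent: float
    n: int
    means: tuple[float, ...] = ()


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x PCs
    explained_percent: np.ndarray
    parameter: str = ""
    loadings: pd.DataFrame | None = None


def _as_groups(values, labels) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise DomainError("values and labels must align")
    return {g: v[lab == g] for g in sorted(pd.unique(lab))}


def gatekeep(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = 0.05,
    levene_center: str = "mean",
) -> str:
    """Choose the testing route from the ANOVA assumptions.

    Returns ``"anova_tukey"`` iff every group passes Shapiro-Wilk and
    Levene's test passes, both at ``alpha``; otherwise
    ``"kruskal_dunn_bh"``.  A zero-variance group makes Shapiro degenerate
    and is treated as a failed normality check.
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(arrays) < 2:
        raise InsufficientDataError("need at least two groups")
    for a in arrays:
        if len(a) < 3:
            raise InsufficientDataError("each group needs n >= 3")
    for a in arrays:
        if np.ptp(a) == 0:  # degenerate: treat as non-normal
            return "kruskal_dunn_bh"
        if stats.shapiro(a).pvalue < alpha:
            return "kruskal_dunn_bh"
    if stats.levene(*arrays, center=levene_center).pvalue < alpha:
        return "kruskal_dunn_bh"
    return "anova_tukey"


def dunn_test(values, labels) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc test after Kruskal-Wallis: unadjusted two-sided
    p-values for all group pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    groups = _as_groups(values, labels)
    v = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(v)
    n_total = len(v)
    # mean rank per group
    offsets = np.cumsum([0] + [len(a) for a in groups.values()])
    mean_rank = {
        g: ranks[offsets[i]:offsets[i + 1]].mean()
        for i, g in enumerate(groups)
    }
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    if var_base <= 0:
        raise DegenerateDataError("all observations tied")
    out: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        se = math.sqrt(var_base * (1 / len(groups[g1]) + 1 / len(groups[g2])))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        out[(g1, g2)] = 2.0 * stats.norm.sf(abs(z))
    return out


def compact_letter_display(
    groups: list[str], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts with one letter covering all groups; every significant pair
    splits each letter-set containing both, and subsets are absorbed.
    Deterministic given the (sorted) group order.  Guarantees: a
    significant pair never shares a letter; a non-significant pair always
    shares at least one.
    """
    order = sorted(groups)
    sets: list[set[str]] = [set(order)]
    for pair in sorted(significant, key=sorted):
        a, b = sorted(pair)
        nxt: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                nxt.append(s - {a})
                nxt.append(s - {b})
            else:
                nxt.append(s)
        # absorb proper subsets and duplicates
        nxt.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for s in nxt:
            if s and not any(s <= t for t in kept):
                kept.append(s)
        sets = kept
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, s in zip(alphabet, sets):
        for g in sorted(s):
            letters[g] += letter
    return letters


def compare_groups(
    values, labels, method: str | None = None, alpha: float = 0.05
) -> ComparisonResult:
    """Global multi-group test plus pairwise comparisons and letters.

    ``method`` is normally chosen by :func:`gatekeep`; pass it explicitly
    to force a route.  Dunn p-values are Benjamini-Hochberg adjusted;
    Tukey's HSD is family-wise by construction.
    """
    groups = _as_groups(values, labels)
    v = np.concatenate(list(groups.values()))
    if np.ptp(v) == 0:
        raise DegenerateDataError("all values identical across all groups")
    if method is None:
        method = gatekeep(groups, alpha=alpha)
    names = sorted(groups)
    if method == "anova_tukey":
        stat, p = stats.f_oneway(*[groups[g] for g in names])
        lab = np.concatenate([[g] * len(groups[g]) for g in names])
        tk = pairwise_tukeyhsd(
            np.concatenate([groups[g] for g in names]), lab, alpha=alpha
        )
        pair_names = [
            (str(a), str(b)) for a, b in itertools.combinations(tk.groupsunique, 2)
        ]
        pairwise = dict(zip(pair_names, np.atleast_1d(tk.pvalues)))
    elif method == "kruskal_dunn_bh":
        stat, p = stats.kruskal(*[groups[g] for g in names])
        raw = dunn_test(values, labels)
        pairs = sorted(raw)
        adj = multipletests([raw[k] for k in pairs], method="fdr_bh")[1]
        pairwise = dict(zip(pairs, adj))
    else:
        raise DomainError(f"unknown method {method!r}")
    significant = {
        frozenset(k) for k, padj in pairwise.items() if padj < alpha
    }
    letters = compact_letter_display(names, significant)
    return ComparisonResult(
        method=method,
        statistic=float(stat),
        pvalue=float(p),
        groups=names,
        pairwise={k: float(x) for k, x in pairwise.items()},
        letters=letters,
        alpha=alpha,
    )


def spearman_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations (average ranks for ties) between
    parameter columns; constant columns yield NaN entries, flagged by the
    caller noticing the NaN."""
    if len(profiles) < 10:
        raise InsufficientDataError("need at least 10 profiles")
    cols = list(profiles.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        x, y = profiles[a].to_numpy(float), profiles[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = stats.spearmanr(x, y).statistic
        out.loc[a, b] = out.loc[b, a] = r
    return out


def cv_across_species(
    species_means, parameter: str = "", organ: str = ""
) -> DispersionSummary:
    """Coefficient of variation (100 * sample SD / mean) over the per-species
    means of one organ — the dispersion statistic used to compare how
    balanced a parameter is across species."""
    means = np.asarray(species_means, dtype=float)
    if means.size < 2:
        raise DomainError("need at least two species means")
    mean = float(means.mean())
    if mean == 0:
        raise DomainError("mean of zero: CV undefined")
    cv = 100.0 * float(means.std(ddof=1)) / mean
    return DispersionSummary(
        parameter=parameter, organ=organ, cv_percent=cv,
        n=int(means.size), means=tuple(float(m) for m in means),
    )


def pca_centered(matrix: pd.DataFrame, parameter: str = "") -> OrdinationResult:
    """Principal component analysis of a complete samples x organs matrix,
    column-centred but *not* scaled to unit variance."""
    if matrix.isna().any().any():
        raise DomainError(
            "matrix has missing cells; drop incomplete individuals first"
        )
    X = matrix.to_numpy(float)
    n_comp = min(X.shape[0] - 1, X.shape[1]) if X.shape[0] > 1 else 1
    pca = PCA(n_components=n_comp)  # sklearn centres, never scales
    scores = pca.fit_transform(X)
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        explained_percent=100.0 * pca.explained_variance_ratio_,
        parameter=parameter,
        loadings=pd.DataFrame(pca.components_.T, index=matrix.columns, columns=pcs),
    )


def standardize(values) -> np.ndarray:
    """z-scores with the sample SD convention: zero mean, unit variance."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("zero standard deviation")
    return (x - x.mean()) / sd
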