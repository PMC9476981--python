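# Methods

## The measurement model

A flow-cytometry DNA-content histogram of an endopolyploid plant tissue is
modelled as a mixture of Gaussian peaks at a 2C anchor channel and its
successive doublings, one peak per endocycle class (4C, 8C, …), over an
exponential debris background below the 2C peak. Peak width is quoted as a
coefficient of variation, so the Gaussian SD is CV · position; well-run
measurements keep G₀/G₁ CVs at 1–5 %. With peaks a factor 2 apart and
CV ≤ 5 %, adjacent classes are separated by ≥ 7 SD, which is what makes
simple gating (rather than mixture deconvolution) adequate.

## Gating

1. **Histogram**: events are binned into 1024 channels, uniform in
   log(intensity) for endopolyploidy screens (how instruments display
   them) or linear for genome-size runs. 1024 bins approximates instrument
   resolution; results are insensitive between 256 and 2048.
2. **Peak detection**: the histogram is smoothed with a 7-bin moving
   average (edge-padded) and local maxima with prominence ≥ 2 % of the
   tallest smoothed bin are kept. Maxima closer than a quarter doubling
   (2^0.25 ≈ 1.19×) are merged, keeping the more prominent — true
   DNA-content peaks sit a factor 2 apart, so anything nearer is binning
   noise on one peak. Peak position is then re-estimated as the
   event-weighted mean within a quarter-doubling window (truncated at
   midpoints to neighbouring peaks), and the window SD/mean gives the peak
   CV.
3. **Doubling-series assignment**: the anchor (2C) is the lowest peak
   whose doubling chain matches at least one other peak; if no chain
   matches anywhere, the tallest peak. Chain consistency is preferred over
   height because the 4C class can dominate roots and stems, while sub-2C
   debris bumps never have doubling partners. Peaks within 10 % of
   anchor · 2^k receive C-level 2 · 2^k; others are flagged unassigned and
   reported, never dropped. The 10 % tolerance is a safe separator given
   peak CV ≤ 5 %.
4. **Series extension**: classes holding a fraction of a percent of nuclei
   (e.g. 64C at 0.03 %) never clear a prominence threshold, yet routine
   practice still counts them because regions are drawn at the expected
   doubling positions. Above the highest detected peak, each successive
   doubling of the anchor window holding ≥ 10 events becomes an assigned
   class; extension stops at the first empty doubling. On real data this
   step could pick up doublet aggregates; the generator does not model
   them, and this is a known limitation.
5. **Gates**: boundaries are the geometric midpoints between adjacent
   assigned peaks — symmetric under the doubling structure — with outer
   boundaries half a doubling (2^±0.5) beyond the extreme peaks. Events
   outside all gates are counted as debris/aggregates and excluded from
   the class total. Inside the outer boundaries this rule is identical to
   nearest-assigned-peak assignment in log space (tested as an oracle
   equivalence). Gating is fully deterministic and scale-invariant.
6. **QC**: genome-size runs need ≥ 5000 nuclei, endopolyploidy screens
   ≥ 3000, and every anchor-peak CV must not exceed 5 %. QC produces a
   report listing each violated rule; pipeline stages exclude failing
   samples with a logged reason rather than silently.

Boundary placement inside FloMax-style manual region drawing is not
reconstructable; the midpoint rule is this package's declared convention.

## Genome size

2C_sample = 2C_standard · (sample G₀/G₁ mean / standard G₀/G₁ mean), with
*Solanum lycopersicum* 'Stupické polní tyčkové rané' (2C = 1.96 pg) as the
default internal standard — a configuration value, not a constant.
Conversions: 1 pg = 978 Mbp; per-chromosome content = 2C / 2n. Each plant
is measured on three days and averaged; the between-day stability metric
is range/mean with a 1.5 % flag threshold (a flag, not an inference).
Species summaries use the sample SD (n − 1). The span statistic is
100 · (max − min)/min over species means.

## Endopolyploidy parameters

With f_k the fraction of nuclei after k endocycles: EI = Σ k·f_k,
MCV = Σ 2^(k+1)·f_k, E4P = Σ_{k≥1} 2^(k+1) n_k / Σ_{k≥1} n_k (undefined —
flagged, never zero — without ≥4C nuclei), ≥4C = 100 · Σ_{k≥1} f_k,
ECmax = max{k : n_k > 0}, meanDNA = MCV · 2C/2 in pg. meanDNA uses the
*species-level* mean 2C, because genome sizes are measured on different
individuals than the endopolyploidy screens. Useful structure: EI, MCV and
≥4C are linear in f (pooled counts ≡ count-weighted index means);
2(1 + EI) ≤ MCV ≤ 2^(ECmax+1), with the left equality iff only 2C/4C
occur. A tissue is called endopolyploid when EI > 0.1.

Replicates (several lateral roots per individual) are averaged as
*indices*, not pooled counts, matching the study convention; pooling is
available separately and is exactly equivalent only for the linear
indices. E4P recomputed from mean class proportions differs from a mean of
per-individual E4P ratios by up to ~0.06 in this data (mean-of-ratios vs
ratio-of-means); report tables round to 2 decimals.

## Comparison layer

Normality (Shapiro–Wilk per group) and homoscedasticity (Levene,
mean-centred by default) are checked at α = 0.05; only if all pass does
the parametric route (one-way ANOVA, Tukey HSD) run, otherwise
Kruskal–Wallis with Dunn's test (rank-sum z with tie correction,
implemented here) under Benjamini–Hochberg adjustment. A zero-variance
group is treated as a failed normality check. Compact letter displays use
the insert-and-absorb procedure over the significant-pair graph with
alphabetical group order; by construction significant pairs never share a
letter and non-significant pairs always share one (asserted on every
run). Spearman correlations use average ranks for ties; no p-values are
attached (magnitudes are the object of interest). Across-species CVs are
100 · sample SD / mean over the per-species organ means. PCAs are
column-centred, never scaled; variance explained sums to 100 % and is
checked against a direct eigendecomposition. Which individuals enter the
PCA is a convention here: individuals with all four non-leaf organs
(root, stem, calyx, corolla), replicate-averaged.

## Synthetic data

The generator reproduces the study conditions: per species × organ cells
with the published mean class proportions and individual counts (N =
19–25; the small leaf cells keep their N of 3 and 22), three replicate
measurements per root (the study took up to five, once seven), 3000
nuclei per endopolyploidy measurement, 5000 for genome-size samples, peak
CV 3 %, debris fraction 2 %. Between-individual variation is a Dirichlet
draw centred on the cell means: it respects the simplex, keeps
zero-mean classes exactly zero, and has one interpretable spread knob.
The default concentration of 60 reproduces the published
between-individual SDs within a factor of two (checked for the largest
cells); the Dirichlet implies weak negative correlations between class
proportions, which the published tables neither confirm nor exclude — an
assumption. Pipeline event simulation draws 20 % more events than the QC
floor so debris exclusion cannot push a clean sample below the
minimum-nuclei rule. The default 2C anchor sits at channel 200; gating is
scale-invariant so the value is cosmetic.

Not modelled: S-phase continua between peaks, doublet aggregates,
fluorescence spillover, and the staining inhibition by secondary
metabolites that makes real leaf samples fail QC — so passing tests
demonstrate correctness of the analysis, not robustness to those
artefacts.

## Problem sizes and determinism

All randomness flows through `numpy.random.Generator` objects seeded
explicitly; a fixed study seed reproduces output files byte-identically.
The analysis drivers run the full published design (~530 count-level
measurements); event-level simulations in tests use n = 5000 events over
50–100 seeds, and the null calibration of Dunn + BH uses 1000 simulated
studies of 4 × 20 observations — sizes chosen so each check is a few
seconds on one core while keeping Monte-Carlo error well below the
asserted tolerances. Recovery behaviour at these sizes: gated class
proportions within 0.02 of truth per class, EI within 0.03, genome-size
ratios within 1 %.

## Known limitations

- Histogram-level peak CV estimates blur with bin width at coarse
  binnings; event-level windows are used wherever events are available.
- The anchor heuristic can mis-anchor if the true 2C class is both rare
  and chainless while a debris bump forms a spurious chain; not observed
  under the generator's conditions.
- E4P's published per-individual averaging cannot be inverted from
  summary tables; recomputations from mean proportions carry the
  documented ~0.06 discrepancy.
- The comparison layer treats measurements as independent; no mixed
  models for locality structure.
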