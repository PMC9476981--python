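#!/usr/bin/env python
"""Between-species and between-organ comparison layer over the simulated
endopolyploidy profiles.

Runs the assumption-gated tests (ANOVA+Tukey or Kruskal-Wallis+Dunn/BH)
with compact letter displays for every parameter, the Spearman matrix of
the four endopolyploidy indices, the across-species CVs of EI, meanDNA and
genome size, centred PCA of individuals x organs, and the standardized
genome-size vs endopolyploidy trend per organ.

Writes results/{comparisons.tsv, spearman.tsv, dispersion.tsv,
pca_*_scores.tsv, trend.tsv}.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from endoflow.groupstats import spearman_matrix
from endoflow.io import read_ploidy_table
from endoflow.pipeline import RunConfig, run_endopoly
from endoflow.reference import genome_size_table

COUNTS = Path("results/simulated/ploidy_counts.tsv")


def main() -> None:
    if not COUNTS.exists():
        subprocess.run([sys.executable, "analysis/01_simulate_study.py"],
                       check=True)
    table = read_ploidy_table(COUNTS)
    gs = genome_size_table()
    result = run_endopoly(table, dict(zip(gs.species, gs.c2_pg)), RunConfig())
    outdir = Path("results")

    comparisons = result["comparisons"]
    comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
    between_species = comparisons.query("within == 'organ' and parameter == 'ei'")
    print("between-species EI tests per organ:")
    print(between_species[["level", "method", "pvalue", "letters"]]
          .to_string(index=False))

    profiles = result["profiles"].dropna(subset=["e4p"])
    sp = spearman_matrix(profiles[["ei", "mcv", "e4p", "p4c"]])
    sp.to_csv(outdir / "spearman.tsv", sep="\t")
    print(f"\nSpearman r(EI, MCV) = {sp.loc['ei', 'mcv']:.2f}, "
          f"r(EI, E4P) = {sp.loc['ei', 'e4p']:.2f}, "
          f"r(E4P, >=4C) = {sp.loc['e4p', 'p4c']:.2f}")

    result["dispersion"].to_csv(outdir / "dispersion.tsv", sep="\t", index=False)
    print("\nacross-species CV (%) per organ and parameter:")
    print(result["dispersion"].round(2).to_string(index=False))

    for key in ("pca_ei", "pca_meandna"):
        ordn = result[key]
        ordn.scores.to_csv(outdir / f"{key}_scores.tsv", sep="\t")
        print(f"{key}: PC1+PC2 explain {ordn.explained_percent[:2].sum():.2f} % "
              "of variance")

    trend = result["trend"]
    trend.to_csv(outdir / "trend.tsv", sep="\t", index=False)
    print("\nstandardized genome-size vs EI trend (Spearman rho per organ):")
    print(trend.round(2).to_string(index=False))
    sign = "negative" if (trend.spearman_ei_vs_gs < 0).all() else "mixed"
    print(f"-> {sign} association between genome size and endopolyploidy "
          "in every organ")


if __name__ == "__main__":
    main()
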