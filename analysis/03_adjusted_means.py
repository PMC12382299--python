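#!/usr/bin/env python
"""Stage-1 mixed models: adjusted genotype means and heritability.

Fits the across-years model (genotype fixed; year, genotype x year,
row-in-year, column-in-year random), the all-random dual for the genotypic
variance, and the pairwise-contrast heritability.  Also writes per-year
adjusted means.
"""

import pandas as pd

from _study import OUT, TRAIT
from testcross_gwas.adjust import means_matrix, trait_summary_table


def main():
    pheno = pd.read_csv(OUT / "phenotypes.tsv", sep="\t")
    summary, summaries = trait_summary_table(pheno, [TRAIT])
    summary.to_csv(OUT / "trait_summary.tsv", sep="\t", index=False)

    means = pd.DataFrame({t: s.adjusted_means for t, s in summaries.items()})
    means.to_csv(OUT / "adjusted_means.tsv", sep="\t", index_label="genotype")
    for year in sorted(pheno["year"].unique()):
        m = means_matrix(pheno, [TRAIT], scope="single_year", year=year)
        m.to_csv(OUT / f"adjusted_means_year{year}.tsv", sep="\t", index_label="genotype")

    s = summaries[TRAIT]
    print(summary.to_string(index=False))
    print(f"\nH^2 = {s.H2:.3f} (sigma2_G = {s.sigma2_G:.3f}, "
          f"v_bar_Delta = {s.v_bar_delta:.3f})")
    if s.mother_means:
        print(f"mother means: {s.mother_means}  (Welch t-test p = {s.t_test_p:.2e})")


if __name__ == "__main__":
    main()
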