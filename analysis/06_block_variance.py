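#!/usr/bin/env python
"""Stage-4 variance partitioning per significant haplotype block.

For every flagged (block, trait) pair, fits the two-GRM mixed model
(block-GRM + rest-GRM + residual) and reports the block ratio
sigma2_gb / (sigma2_gr + sigma2_e) alongside the conventional proportion
of total variance.
"""

import pandas as pd

from _study import OUT
from testcross_gwas.blocks import HaplotypeBlock
from testcross_gwas.blockvar import block_variance, block_variance_table
from testcross_gwas.gwas import marker_pca
from testcross_gwas.qc import GenotypeMatrix, impute_mean


def main():
    geno = GenotypeMatrix.read(OUT / "genotypes_qc.tsv", OUT / "marker_map_qc.tsv")
    imputed = impute_mean(geno)
    means = pd.read_csv(OUT / "adjusted_means.tsv", sep="\t", index_col="genotype")
    pheno = pd.read_csv(OUT / "phenotypes.tsv", sep="\t")
    hybrids = pheno.drop_duplicates("genotype").set_index("genotype")[["father", "mother"]]
    blocks_tab = pd.read_csv(OUT / "blocks.tsv", sep="\t")
    gwas = pd.read_csv(OUT / "gwas.tsv", sep="\t")
    pcs = marker_pca(imputed, k=3)

    results = []
    marker_order = list(geno.marker_map.index)
    for _, row in blocks_tab[blocks_tab["significant"]].iterrows():
        members = [m for m in marker_order
                   if geno.marker_map.loc[m, "chromosome"] == row["chromosome"]
                   and row["start_bp"] <= geno.marker_map.loc[m, "pos"] <= row["end_bp"]]
        block = HaplotypeBlock(row["block"], row["chromosome"], members,
                               int(row["start_bp"]), int(row["end_bp"]))
        for trait in str(row["traits"]).split(";"):
            results.append(block_variance(means[trait], block, imputed, hybrids,
                                          pcs, trait=trait))
    tab = block_variance_table(results)
    tab.to_csv(OUT / "block_variance.tsv", sep="\t", index=False)
    if len(tab):
        show = tab.copy()
        show["ratio_pct"] = 100 * show["ratio"]
        show["alt_ratio_pct"] = 100 * show["alt_ratio"]
        print(show[["block", "trait", "sigma2_gb", "sigma2_gr", "sigma2_e",
                    "ratio_pct", "alt_ratio_pct"]].round(3).to_string(index=False))
    else:
        print("no significant blocks to partition")


if __name__ == "__main__":
    main()
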