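#!/usr/bin/env python
"""Stage-3 haplotype blocks: greedy LD blocks with a 12-marker tolerance.

Builds blocks per chromosome (r^2 >= 0.4 to the conforming edge, up to 12
interspersed non-conforming markers), flags blocks containing a significant
GWAS marker, and enumerates haplotype alleles of the flagged blocks with
their per-allele trait summaries.
"""

import pandas as pd

from _study import OUT
from testcross_gwas.blocks import (alleles_table, blocks_table, build_blocks_genome,
                                   enumerate_alleles, flag_blocks)
from testcross_gwas.qc import GenotypeMatrix, impute_mean


def main():
    geno = GenotypeMatrix.read(OUT / "genotypes_qc.tsv", OUT / "marker_map_qc.tsv")
    imputed = impute_mean(geno)
    gwas = pd.read_csv(OUT / "gwas.tsv", sep="\t")
    means = pd.read_csv(OUT / "adjusted_means.tsv", sep="\t", index_col="genotype")
    pheno = pd.read_csv(OUT / "phenotypes.tsv", sep="\t")
    hybrids = pheno.drop_duplicates("genotype").set_index("genotype")[["father", "mother"]]

    blocks = build_blocks_genome(imputed, geno.marker_map, r2_min=0.4, tolerance=12)
    blocks, singletons = flag_blocks(blocks, gwas, threshold=1e-3)
    blocks_table(blocks, gwas).to_csv(OUT / "blocks.tsv", sep="\t", index=False)
    singletons.to_csv(OUT / "significant_singletons.tsv", sep="\t", index=False)

    flagged = [b for b in blocks if b.significant]
    print(f"{len(blocks)} haplotype blocks; {len(flagged)} significant; "
          f"{len(singletons)} significant singleton markers")
    for b in flagged:
        print(f"  {b.id} {b.chromosome}:{b.start_bp}-{b.end_bp} "
              f"({b.span_kbp} kbp, {b.n_markers} markers) traits={b.traits}")

    values = (means.reset_index().rename(columns={"genotype": "hybrid"})
              .assign(father=lambda d: d["hybrid"].map(hybrids["father"]))
              .drop(columns=["hybrid"]))
    rows = []
    for b in flagged:
        alleles = enumerate_alleles(b, geno.dosages, values, min_carriers=3)
        rows.append(alleles_table(alleles))
        print(f"  {b.id}: {sum(a.pattern is not None for a in alleles)} alleles "
              f"with >= 3 carriers")
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(OUT / "alleles.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
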