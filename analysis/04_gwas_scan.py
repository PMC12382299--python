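#!/usr/bin/env python
"""Stage-2 GWAS: VanRaden GRM, marker PCA, per-marker mixed-model scan.

Scans every post-QC marker against the adjusted means with the kinship
mixed model (mother + 3 PCs fixed), flags p <= 1e-3, and reports whether
the planted QTL markers were hit.
"""

import json

import pandas as pd

from _study import OUT
from testcross_gwas.gwas import gwas_scan, marker_pca, vanraden_grm
from testcross_gwas.qc import GenotypeMatrix, impute_mean


def main():
    geno = GenotypeMatrix.read(OUT / "genotypes_qc.tsv", OUT / "marker_map_qc.tsv")
    imputed = impute_mean(geno)
    means = pd.read_csv(OUT / "adjusted_means.tsv", sep="\t", index_col="genotype")
    pheno = pd.read_csv(OUT / "phenotypes.tsv", sep="\t")
    hybrids = pheno.drop_duplicates("genotype").set_index("genotype")[["father", "mother"]]
    h2 = pd.read_csv(OUT / "trait_summary.tsv", sep="\t").set_index("trait")["H2"]

    grm = vanraden_grm(imputed)
    pcs = marker_pca(imputed, k=3)
    res = gwas_scan(means, hybrids, imputed, grm, pcs, marker_map=geno.marker_map,
                    h2=h2, threshold=1e-3, gate_h2=0.1)
    res.table.to_csv(OUT / "gwas.tsv", sep="\t", index=False)

    sig = res.table[res.table["significant"]]
    print(f"{len(sig)} significant marker-trait associations (p <= 1e-3) "
          f"of {len(res.table)} tests")
    print(sig.nlargest(min(8, len(sig)), "neg_log10_p")
          [["marker", "chromosome", "pos", "effect", "p"]].to_string(index=False))

    truth = json.loads((OUT / "sim_truth.json").read_text())
    qtl = [q[0] for q in truth["qtl_markers"]]
    hit = res.table[res.table["marker"].isin(qtl) & res.table["significant"]]
    print(f"\nplanted QTL markers recovered: {len(hit)}/{len(qtl)} ({list(hit['marker'])})")


if __name__ == "__main__":
    main()
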