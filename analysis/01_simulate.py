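#!/usr/bin/env python
"""Simulate the synthetic testcross study and write the raw data bundle.

Writes genotypes (fathers x markers), the marker map, the plot-level
phenotype table and the ground-truth sidecar under results/study/.
"""

from _study import OUT, STUDY, TRAIT
from testcross_gwas.simulate import simulate_all


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    geno, pheno, truth = simulate_all(STUDY, trait=TRAIT)
    geno.write(OUT / "genotypes.tsv", OUT / "marker_map.tsv")
    pheno.to_csv(OUT / "phenotypes.tsv", sep="\t", index=False)
    truth.write(OUT / "sim_truth.json")

    n_rep = (pheno.groupby(["year", "genotype"]).size() == 2).groupby("year").sum()
    print(f"simulated {len(geno.ids)} father lines x {len(geno.markers)} markers")
    print(f"{pheno['genotype'].nunique()} hybrids, {len(pheno)} plots over "
          f"{pheno['year'].nunique()} years; replicated entries per year: "
          f"{n_rep.to_dict()}")
    print(f"planted QTL markers: {[m for m, _, _ in truth.qtl_markers]}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
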