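#!/usr/bin/env python
"""Stage-5 overlap of flagged blocks with externally positioned QTL.

A real analysis consumes a table of literature QTL positions on the working
reference.  Here the table is synthesised from the simulation truth (the
planted QTL positions), so the expected outcome is known: every planted QTL
should fall inside a flagged block.
"""

import json

import pandas as pd

from _study import OUT
from testcross_gwas.blocks import HaplotypeBlock
from testcross_gwas.overlap import overlap
from testcross_gwas.qc import GenotypeMatrix


def main():
    geno = GenotypeMatrix.read(OUT / "genotypes_qc.tsv", OUT / "marker_map_qc.tsv")
    blocks_tab = pd.read_csv(OUT / "blocks.tsv", sep="\t")
    truth = json.loads((OUT / "sim_truth.json").read_text())

    qtl_rows = [{"study": "synthetic_truth", "trait": "trait", "chromosome": chrom,
                 "pos": int(geno.marker_map.loc[marker, "pos"])}
                for marker, chrom, _ in truth["qtl_markers"]
                if marker in geno.marker_map.index]
    qtls = pd.DataFrame(qtl_rows)
    qtls.to_csv(OUT / "literature_qtl_synthetic.tsv", sep="\t", index=False)

    blocks = []
    for _, r in blocks_tab.iterrows():
        b = HaplotypeBlock(r["block"], r["chromosome"], [], int(r["start_bp"]),
                           int(r["end_bp"]))
        b.significant = bool(r["significant"])
        b.traits = str(r["traits"]).split(";") if isinstance(r["traits"], str) else []
        blocks.append(b)

    ov = overlap(blocks, qtls)
    ov.to_csv(OUT / "qtl_overlap.tsv", sep="\t", index=False)
    print(f"{len(ov)} of {len(qtls)} planted QTL positions fall inside a "
          f"flagged haplotype block")
    if len(ov):
        print(ov.to_string(index=False))


if __name__ == "__main__":
    main()
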