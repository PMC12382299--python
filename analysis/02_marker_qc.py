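#!/usr/bin/env python
"""Marker quality control: het calls to missing, MAF and missingness filters.

Reads the raw genotypes from 01, applies the inclusive filters (MAF <= 0.05,
missing rate >= 5%), and writes the analysis-ready matrix plus the QC report.
"""

from _study import OUT
from testcross_gwas.qc import GenotypeMatrix, run_qc


def main():
    geno = GenotypeMatrix.read(OUT / "genotypes.tsv", OUT / "marker_map.tsv")
    filtered, report = run_qc(geno)
    filtered.write(OUT / "genotypes_qc.tsv", OUT / "marker_map_qc.tsv")
    report.to_frame().to_csv(OUT / "qc_report.tsv", sep="\t", index=False)
    print(report.to_frame().to_string(index=False))
    print(f"retained {report.retained}/{report.n_input} markers -> genotypes_qc.tsv")


if __name__ == "__main__":
    main()
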