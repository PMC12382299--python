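"""Shared configuration for the numbered analysis drivers.

The synthetic study mirrors the real design this pipeline targets: 162
homozygous father lines crossed to two maternal testers (324 testcross
hybrids), chromosome-structured markers in LD blocks with 10% non-locus-
specific noise markers, a two-year p-rep field layout with ~15% replicated
entries, and one trait built from mother, QTL, polygenic, year, G x E,
row/column and residual effects.  Drivers read and write under results/study.
"""

from pathlib import Path

from testcross_gwas.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "study"

STUDY = SimConfig(
    n_fathers=162, n_chromosomes=5, markers_per_chromosome=120,
    ld_block_length=10, within_block_corr=0.85, noise_marker_fraction=0.1,
    n_testers=2, replicated_fraction=0.15, n_years=2,
    qtl_spec=[(0, 3, 1.2), (2, 7, 0.9)],
    variance_spec=(1.0, 0.5, 0.3, 0.2, 0.2, 1.0),
    mother_effect=1.0,
    seed=2024,
)

TRAIT = "trait"
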