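"""End-to-end orchestration: simulate -> QC -> adjusted means -> GWAS ->
haplotype blocks -> block variance -> QTL overlap.

Every stage writes a TSV under the output directory so each downstream
stage is re-derivable from persisted intermediates, and a run log records
seeds, thresholds and package version.  All thresholds default to the
values of the source analysis (MAF 0.05, missing 5%, 3 PCs, p <= 1e-3,
H^2 gate 0.1, r^2 >= 0.4, tolerance 12).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, adjust, blocks as hb, blockvar, gwas as gw, overlap as ov, qc
from .simulate import SimConfig, simulate_all

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    # input files; None for each means "simulate instead"
    genotypes: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    keep_list: str | None = None
    qtl_table: str | None = None
    traits: list = field(default_factory=lambda: ["trait"])
    maf_min: float = 0.05
    miss_max: float = 0.05
    n_pcs: int = 3
    gwas_method: str = "exact"
    gwas_threshold: float = 1e-3
    gate_h2: float = 0.1
    r2_min: float = 0.4
    tolerance: int = 12
    min_carriers: int = 3
    simulation: SimConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            if "qtl_spec" in sim:
                sim["qtl_spec"] = [tuple(q) for q in sim["qtl_spec"]]
            if "variance_spec" in sim:
                sim["variance_spec"] = tuple(sim["variance_spec"])
            cfg.simulation = SimConfig(**sim)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, lo, hi in (("maf_min", 0, 0.5), ("miss_max", 0, 1),
                             ("gwas_threshold", 0, 1), ("gate_h2", 0, 1),
                             ("r2_min", 0, 1)):
            v = float(getattr(self, name))
            if not lo <= v <= hi:
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")
        if int(self.tolerance) < 0 or int(self.n_pcs) < 0:
            raise ValueError("tolerance and n_pcs must be >= 0")
        if self.gwas_method not in ("exact", "p3d"):
            raise ValueError(f"config gwas_method={self.gwas_method!r} not in (exact, p3d)")


def validate_inputs(geno: qc.GenotypeMatrix, pheno: pd.DataFrame,
                    hybrids: pd.DataFrame) -> list[str]:
    """Key-consistency checks; returns problems (empty list = pass)."""
    problems = []
    for i, (gid, father) in enumerate(hybrids["father"].items()):
        if father not in geno.dosages.index:
            problems.append(f"hybrid {gid!r} (row {i}): father {father!r} not genotyped")
    unknown = set(pheno["genotype"]) - set(hybrids.index)
    for g in sorted(unknown):
        problems.append(f"phenotype genotype id {g!r} has no hybrid mapping")
    m = geno.marker_map
    order = m.sort_values(["chromosome", "pos"], kind="stable").index
    if not order.equals(m.index):
        for i in range(len(m) - 1):
            a, b = m.index[i], m.index[i + 1]
            if (m.loc[a, "chromosome"] == m.loc[b, "chromosome"]
                    and m.loc[a, "pos"] > m.loc[b, "pos"]):
                problems.append(f"marker map unsorted at lines {i + 1}/{i + 2}: {a} > {b}")
                break
    dup = pheno.duplicated(subset=[c for c in ("genotype", "year", "row", "column")
                                   if c in pheno.columns])
    if dup.any():
        problems.append(f"{int(dup.sum())} duplicate (genotype, year, row, column) plots")
    return problems


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a bundle of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = []

    def note(msg):
        log.info(msg)
        run_log.append(msg)

    note(f"testcross-gwas {__version__} | seed={config.seed}")
    note(f"thresholds: maf<= {config.maf_min}, miss>= {config.miss_max}, "
         f"PCs={config.n_pcs}, p<= {config.gwas_threshold}, H2 gate {config.gate_h2}, "
         f"r2>= {config.r2_min}, tolerance {config.tolerance}")

    # --- stage: simulate or load -------------------------------------------
    try:
        if config.genotypes is None:
            sim = config.simulation or SimConfig()
            sim = dataclasses.replace(sim, seed=int(config.seed))
            geno_raw, pheno, truth = simulate_all(sim, trait=config.traits[0])
            geno_raw.write(out / "genotypes.tsv", out / "marker_map.tsv")
            pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
            truth.write(out / "sim_truth.json")
            note(f"simulated {len(geno_raw.ids)} fathers x {len(geno_raw.markers)} markers, "
                 f"{len(pheno)} plots")
        else:
            geno_raw = qc.GenotypeMatrix.read(config.genotypes, config.marker_map)
            pheno = pd.read_csv(config.phenotypes, sep="\t")
            truth = None
    except (ValueError, OSError) as exc:
        raise StageError("simulate", "E_INPUT", str(exc)) from exc

    hybrids = (pheno.drop_duplicates("genotype").set_index("genotype")[["father", "mother"]]
               if "father" in pheno.columns else None)
    if hybrids is None:
        raise StageError("simulate", "E_INPUT", "phenotype table needs a 'father' column")
    problems = validate_inputs(geno_raw, pheno, hybrids)
    if problems:
        raise StageError("validate", "E_KEYS", "; ".join(problems[:10]))

    # --- stage: qc ----------------------------------------------------------
    try:
        keep = None
        if config.keep_list:
            keep = [line.strip() for line in Path(config.keep_list).read_text().splitlines()
                    if line.strip()]
        geno, report = qc.run_qc(geno_raw, keep=keep,
                                 maf_min=config.maf_min, miss_max=config.miss_max)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        geno.write(out / "genotypes_qc.tsv", out / "marker_map_qc.tsv")
        imputed = qc.impute_mean(geno)
        note(f"QC: retained {report.retained}/{report.n_input} markers")
    except ValueError as exc:
        raise StageError("qc", "E_QC", str(exc)) from exc

    # --- stage: adjusted means & heritability -------------------------------
    try:
        summary_tab, summaries = adjust.trait_summary_table(pheno, config.traits)
        summary_tab.to_csv(out / "trait_summary.tsv", sep="\t", index=False)
        means = pd.DataFrame({t: s.adjusted_means for t, s in summaries.items()})
        means.to_csv(out / "adjusted_means.tsv", sep="\t", index_label="genotype")
        h2 = pd.Series({t: s.H2 for t, s in summaries.items()})
        note("H2: " + ", ".join(f"{t}={v:.3f}" for t, v in h2.items()))
    except ValueError as exc:
        raise StageError("adjust", "E_MODEL", str(exc)) from exc

    # --- stage: gwas --------------------------------------------------------
    try:
        grm = gw.vanraden_grm(imputed)
        pcs = gw.marker_pca(imputed, k=config.n_pcs)
        scan = gw.gwas_scan(means, hybrids, imputed, grm, pcs,
                            marker_map=geno.marker_map, h2=h2,
                            threshold=config.gwas_threshold, gate_h2=config.gate_h2,
                            method=config.gwas_method)
        scan.table.to_csv(out / "gwas.tsv", sep="\t", index=False)
        n_sig = int(scan.table["significant"].sum())
        note(f"GWAS: {n_sig} significant marker-trait pairs; "
             f"skipped traits below gate: {scan.skipped_traits}")
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise StageError("gwas", "E_GWAS", str(exc)) from exc

    # --- stage: haplotype blocks --------------------------------------------
    try:
        blocks = hb.build_blocks_genome(imputed, geno.marker_map,
                                        r2_min=config.r2_min, tolerance=config.tolerance)
        blocks, singletons = hb.flag_blocks(blocks, scan.table, config.gwas_threshold)
        hb.blocks_table(blocks, scan.table).to_csv(out / "blocks.tsv", sep="\t", index=False)
        singletons.to_csv(out / "significant_singletons.tsv", sep="\t", index=False)
        flagged = [b for b in blocks if b.significant]
        note(f"blocks: {len(blocks)} built, {len(flagged)} significant, "
             f"{len(singletons)} significant singleton markers")
        allele_rows = []
        for b in flagged:
            alleles = hb.enumerate_alleles(
                b, geno.dosages,
                means.reset_index().rename(columns={"genotype": "hybrid"})
                     .assign(father=lambda d: d["hybrid"].map(hybrids["father"]))
                     .drop(columns=["hybrid"]),
                min_carriers=config.min_carriers)
            allele_rows.append(hb.alleles_table(alleles))
        alleles_tab = (pd.concat(allele_rows, ignore_index=True) if allele_rows
                       else pd.DataFrame(columns=["block", "allele", "pattern", "n_carriers",
                                                  "trait", "n_values", "mean", "median", "q1", "q3"]))
        alleles_tab.to_csv(out / "alleles.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise StageError("blocks", "E_BLOCKS", str(exc)) from exc

    # --- stage: block variance ----------------------------------------------
    try:
        bv_results = []
        for b in flagged:
            for trait in b.traits:
                bv_results.append(blockvar.block_variance(
                    means[trait], b, imputed, hybrids, pcs, trait=trait))
        bv_tab = blockvar.block_variance_table(bv_results)
        bv_tab.to_csv(out / "block_variance.tsv", sep="\t", index=False)
        if len(bv_tab):
            note(f"block variance: top ratio {bv_tab['ratio'].max():.4f} "
                 f"(block {bv_tab.loc[bv_tab['ratio'].idxmax(), 'block']})")
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise StageError("blockvar", "E_BLOCKVAR", str(exc)) from exc

    # --- stage: qtl overlap ---------------------------------------------------
    try:
        if config.qtl_table:
            qtls = ov.read_qtl_table(config.qtl_table)
            ov_tab = ov.overlap(blocks, qtls)
        else:
            ov_tab = pd.DataFrame(columns=["block", "chromosome", "block_start_bp",
                                           "block_end_bp", "block_traits",
                                           "qtl_study", "qtl_trait", "qtl_pos"])
        ov_tab.to_csv(out / "qtl_overlap.tsv", sep="\t", index=False)
        note(f"QTL overlap: {len(ov_tab)} (block, QTL) pairs")
    except ValueError as exc:
        raise StageError("overlap", "E_OVERLAP", str(exc)) from exc

    # --- summary --------------------------------------------------------------
    per_trait = []
    for t in means.columns:
        sub = scan.table[scan.table["trait"] == t]
        per_trait.append({
            "trait": t, "H2": float(h2[t]),
            "n_significant_markers": int(sub["significant"].sum()) if len(sub) else 0,
            "n_flagged_blocks": sum(t in b.traits for b in flagged),
            "top_block_ratio": (float(bv_tab[bv_tab["trait"] == t]["ratio"].max())
                                if len(bv_tab) and (bv_tab["trait"] == t).any() else float("nan")),
        })
    pd.DataFrame(per_trait).to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "run_log.txt").write_text("\n".join(run_log) + "\n")
    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=str)

    return {"geno": geno, "report": report, "pheno": pheno, "hybrids": hybrids,
            "means": means, "h2": h2, "summaries": summaries, "grm": grm, "pcs": pcs,
            "scan": scan, "blocks": blocks, "flagged": flagged,
            "block_variance": bv_tab, "overlap": ov_tab, "truth": truth,
            "out_dir": out}
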