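"""Synthetic testcross-hybrid data with known ground truth.

The generator emulates the study system the pipeline is built for: a panel
of fully homozygous father lines (dosages 0/2 only), each crossed to two
maternal testers to give one F1 hybrid per (father, tester) pair; markers
arranged on chromosomes in LD blocks, with a fraction of "noise" markers
that carry no positional signal; and a two-year partially replicated
(p-rep) field layout on a row x column grid.  Phenotypes are built from a
mother effect, planted QTL-block effects, a polygenic term drawn against
the fathers' genomic relationship matrix, and year, genotype x year, row,
column and residual draws.

Within an LD block the dosages follow a Markov copy process: each marker
copies the previous marker's founder allele with probability
``sqrt(within_block_corr)`` and otherwise redraws from the block's allele
frequency, giving expected adjacent-pair r^2 equal to ``within_block_corr``.
Three independent pseudo-random streams (genotypes, design, phenotypes) are
spawned from the seed so that changing one component leaves the others
untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gwas import vanraden_grm
from .qc import GenotypeMatrix


@dataclass
class SimConfig:
    n_fathers: int = 162
    n_chromosomes: int = 5
    markers_per_chromosome: int = 120
    ld_block_length: int = 10
    within_block_corr: float = 0.85
    noise_marker_fraction: float = 0.1
    n_testers: int = 2
    replicated_fraction: float = 0.15
    n_years: int = 2
    # (chromosome index 0-based, block index 0-based, additive effect per dosage unit)
    qtl_spec: list = field(default_factory=list)
    # (polygenic, year, GxE, row, col, residual) variances in squared trait units
    variance_spec: tuple = (1.0, 0.5, 0.3, 0.2, 0.2, 1.0)
    mother_effect: float = 1.0
    intercept: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_fathers", "n_chromosomes", "markers_per_chromosome",
                     "ld_block_length", "n_testers", "n_years"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"invalid SimConfig.{name}: must be >= 1")
        for name in ("within_block_corr", "noise_marker_fraction", "replicated_fraction"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid SimConfig.{name}: must lie in [0, 1]")
        if len(self.variance_spec) != 6 or any(v < 0 for v in self.variance_spec):
            raise ValueError("invalid SimConfig.variance_spec: six variances, all >= 0")
        n_blocks = self.markers_per_chromosome // self.ld_block_length
        for q in self.qtl_spec:
            chrom, block, _ = q
            if not (0 <= chrom < self.n_chromosomes):
                raise ValueError(f"invalid SimConfig.qtl_spec: chromosome {chrom} out of range")
            if not (0 <= block < max(n_blocks, 1)):
                raise ValueError(f"invalid SimConfig.qtl_spec: block {block} out of range")


@dataclass
class SimTruth:
    """Everything a recovery test needs, reproducible from (config, seed)."""

    qtl_markers: list          # (marker id, chromosome label, effect)
    polygenic: pd.Series       # per-father polygenic value
    variance_spec: tuple
    mother_effect: float
    intercept: float
    block_bounds: pd.DataFrame  # chromosome, block index, first/last marker id, is QTL block
    noise_markers: list
    year_effects: dict
    config: SimConfig = None

    def write(self, path) -> None:
        payload = {
            "qtl_markers": [list(q) for q in self.qtl_markers],
            "polygenic": self.polygenic.to_dict(),
            "variance_spec": list(self.variance_spec),
            "mother_effect": self.mother_effect,
            "intercept": self.intercept,
            "noise_markers": list(self.noise_markers),
            "year_effects": self.year_effects,
            "block_bounds": self.block_bounds.to_dict(orient="list"),
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _streams(seed: int):
    """One independent child stream per logical component."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in children)


def chrom_label(i: int) -> str:
    return f"A{i + 1:02d}"


def simulate_founders(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, list]:
    """Homozygous founder dosages with block LD plus noise markers.

    Returns ``(geno, block_bounds, noise_markers)``; dosages are strictly
    0/2 (no missing calls are simulated).
    """
    config.validate()
    rng, _, _ = _streams(config.seed)
    n, mpc = config.n_fathers, config.markers_per_chromosome
    copy_p = float(np.sqrt(config.within_block_corr))
    ids = [f"F{i + 1:03d}" for i in range(n)]

    cols, chroms, positions = [], [], []
    alleles = np.empty((n, config.n_chromosomes * mpc), dtype=np.int8)
    bounds = []
    j = 0
    for c in range(config.n_chromosomes):
        pos = np.cumsum(rng.integers(20_000, 80_000, size=mpc))
        block_of = np.minimum(np.arange(mpc) // config.ld_block_length,
                              mpc // config.ld_block_length - 1 if mpc >= config.ld_block_length else 0)
        start_j = j
        prev = None
        for m in range(mpc):
            b = block_of[m]
            if m == 0 or b != block_of[m - 1]:
                freq = rng.uniform(0.1, 0.9)
                a = (rng.random(n) < freq).astype(np.int8)
                block_freq = freq
            else:
                redraw = rng.random(n) >= copy_p
                a = prev.copy()
                a[redraw] = (rng.random(int(redraw.sum())) < block_freq).astype(np.int8)
            alleles[:, j] = a
            prev = a
            cols.append(f"m_{chrom_label(c)}_{m + 1:04d}")
            chroms.append(chrom_label(c))
            positions.append(int(pos[m]))
            j += 1
        for b in np.unique(block_of):
            sel = np.where(block_of == b)[0]
            bounds.append({"chromosome": chrom_label(c), "block": int(b),
                           "first_marker": cols[start_j + sel[0]],
                           "last_marker": cols[start_j + sel[-1]]})

    # overwrite a random subset of columns with position-independent draws
    n_noise = int(round(config.noise_marker_fraction * len(cols)))
    noise_idx = np.sort(rng.choice(len(cols), size=n_noise, replace=False)) if n_noise else np.array([], int)
    for k in noise_idx:
        freq = rng.uniform(0.1, 0.9)
        alleles[:, k] = (rng.random(n) < freq).astype(np.int8)
    noise_markers = [cols[k] for k in noise_idx]

    dosages = pd.DataFrame(2.0 * alleles, index=ids, columns=cols)
    marker_map = pd.DataFrame({"chromosome": chroms, "pos": positions}, index=pd.Index(cols, name="marker"))
    return GenotypeMatrix(dosages, marker_map), pd.DataFrame(bounds), noise_markers


def hybrid_id(father: str, tester: str) -> str:
    return f"{father}x{tester}"


def tester_labels(n_testers: int) -> list[str]:
    return [chr(ord("A") + t) for t in range(n_testers)]


def simulate_design(config: SimConfig) -> pd.DataFrame:
    """p-rep field layout: every hybrid once per year, a random
    ``replicated_fraction`` of hybrids twice, on a rectangular grid with
    complete randomization within year."""
    config.validate()
    _, rng, _ = _streams(config.seed)
    fathers = [f"F{i + 1:03d}" for i in range(config.n_fathers)]
    testers = tester_labels(config.n_testers)
    entries = [(f, t) for f in fathers for t in testers]
    n_entries = len(entries)
    n_rep = int(round(config.replicated_fraction * n_entries))

    rows = []
    for year in range(1, config.n_years + 1):
        rep_idx = rng.choice(n_entries, size=n_rep, replace=False) if n_rep else np.array([], int)
        plots = list(entries) + [entries[i] for i in rep_idx]
        n_plots = len(plots)
        n_rows = int(np.ceil(np.sqrt(n_plots)))
        n_cols = int(np.ceil(n_plots / n_rows))
        if n_rows * n_cols < n_plots:
            raise ValueError(f"field grid {n_rows}x{n_cols} too small for {n_plots} plots")
        cells = [(r + 1, c + 1) for r in range(n_rows) for c in range(n_cols)]
        order = rng.permutation(len(cells))[:n_plots]
        for (f, t), ci in zip(plots, order):
            r, c = cells[ci]
            rows.append({"genotype": hybrid_id(f, t), "father": f, "mother": t,
                         "year": year, "row": r, "column": c})
    return pd.DataFrame(rows)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    design: pd.DataFrame,
    config: SimConfig,
    block_bounds: pd.DataFrame | None = None,
    noise_markers: list | None = None,
    trait: str = "trait",
) -> tuple[pd.DataFrame, SimTruth]:
    """Add a trait column to the design table and return it with the truth.

    plot value = intercept + mother_effect * 1[tester != A]
               + sum_q effect_q * (dosage_q - mean dosage_q)
               + polygenic(father) + year + GxE + row(year) + col(year) + resid
    """
    config.validate()
    _, _, rng = _streams(config.seed)
    s2_poly, s2_year, s2_gxe, s2_row, s2_col, s2_resid = map(float, config.variance_spec)

    if block_bounds is None or noise_markers is None:
        _, block_bounds, noise_markers = simulate_founders(config)

    # QTL markers: middle marker of the named structured block
    qtl_markers = []
    for chrom, block, eff in config.qtl_spec:
        lab = chrom_label(int(chrom))
        row = block_bounds[(block_bounds["chromosome"] == lab) & (block_bounds["block"] == int(block))]
        if row.empty:
            raise ValueError(f"qtl_spec names unknown block ({chrom}, {block})")
        first, last = row.iloc[0][["first_marker", "last_marker"]]
        members = list(geno.marker_map.index)
        i0, i1 = members.index(first), members.index(last)
        qtl_markers.append((members[(i0 + i1) // 2], lab, float(eff)))

    fathers = list(geno.ids)
    if s2_poly > 0:
        grm = vanraden_grm(geno.dosages).matrix.to_numpy()
        # unit mean diagonal so s2_poly is the average genetic variance per
        # hybrid (fully homozygous lines have mean GRM diagonal near 2)
        grm = grm / np.mean(np.diag(grm))
        # small ridge keeps the Cholesky factor defined for rank-deficient GRMs
        L = np.linalg.cholesky(s2_poly * grm + 1e-8 * np.eye(len(fathers)))
        poly = pd.Series(L @ rng.standard_normal(len(fathers)), index=fathers)
    else:
        poly = pd.Series(0.0, index=pd.Index(fathers))

    years = sorted(design["year"].unique())
    year_eff = {int(y): rng.normal(0.0, np.sqrt(s2_year)) for y in years}
    gxe_keys = design[["genotype", "year"]].drop_duplicates()
    gxe = {(g, int(y)): rng.normal(0.0, np.sqrt(s2_gxe)) for g, y in gxe_keys.itertuples(index=False)}
    row_keys = design[["year", "row"]].drop_duplicates()
    row_eff = {(int(y), int(r)): rng.normal(0.0, np.sqrt(s2_row)) for y, r in row_keys.itertuples(index=False)}
    col_keys = design[["year", "column"]].drop_duplicates()
    col_eff = {(int(y), int(c)): rng.normal(0.0, np.sqrt(s2_col)) for y, c in col_keys.itertuples(index=False)}

    ref_tester = tester_labels(config.n_testers)[0]
    qtl_dev = np.zeros(len(design))
    for marker, _, eff in qtl_markers:
        d = geno.dosages[marker]
        centered = design["father"].map(d - d.mean()).to_numpy()
        qtl_dev = qtl_dev + eff * centered

    values = (
        config.intercept
        + config.mother_effect * (design["mother"] != ref_tester).to_numpy(dtype=float)
        + qtl_dev
        + design["father"].map(poly).to_numpy()
        + design["year"].map(lambda y: year_eff[int(y)]).to_numpy()
        + np.array([gxe[(g, int(y))] for g, y in design[["genotype", "year"]].itertuples(index=False)])
        + np.array([row_eff[(int(y), int(r))] for y, r in design[["year", "row"]].itertuples(index=False)])
        + np.array([col_eff[(int(y), int(c))] for y, c in design[["year", "column"]].itertuples(index=False)])
        + rng.normal(0.0, np.sqrt(s2_resid), size=len(design))
    )
    pheno = design.copy()
    pheno[trait] = values

    is_qtl_block = []
    qtl_blocks = {(c, b) for c, b, _ in config.qtl_spec}
    for _, r in block_bounds.iterrows():
        ci = int(r["chromosome"][1:]) - 1
        is_qtl_block.append((ci, int(r["block"])) in qtl_blocks)
    bb = block_bounds.copy()
    bb["is_qtl"] = is_qtl_block

    truth = SimTruth(
        qtl_markers=qtl_markers,
        polygenic=poly,
        variance_spec=tuple(config.variance_spec),
        mother_effect=config.mother_effect,
        intercept=config.intercept,
        block_bounds=bb,
        noise_markers=list(noise_markers),
        year_effects={str(k): v for k, v in year_eff.items()},
        config=config,
    )
    return pheno, truth


def simulate_all(config: SimConfig, trait: str = "trait"):
    """Convenience wrapper: founders + design + phenotypes in one call."""
    geno, bounds, noise = simulate_founders(config)
    design = simulate_design(config)
    pheno, truth = simulate_phenotypes(geno, design, config, bounds, noise, trait=trait)
    return geno, pheno, truth
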