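"""Stage 3: pairwise LD, greedy tolerance-based haplotype blocks, and
haplotype-allele effect summaries.

Blocks are built per chromosome from the map-ordered marker sequence:

1. seed with the unassigned adjacent marker pair of highest r^2 (leftmost
   pair on ties); the seed is admitted only if its r^2 >= ``r2_min``;
2. extend outward in both directions: a candidate joins when its r^2 with
   the nearest *conforming* edge marker reaches the threshold; up to
   ``tolerance`` consecutive non-conforming markers may be skipped and are
   absorbed into the block only if a later marker conforms again (the skip
   counter resets on every absorption);
3. close the block at the outermost conforming markers, mark its members
   assigned, and look for the next seed; stop when no admissible seed
   remains.

Blocks therefore never overlap and their member lists are contiguous in map
order.  Non-conforming markers absorbed by the tolerance rule count as
members for span and allele enumeration but are never used as LD anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    id: str
    chromosome: str
    markers: list            # ordered by bp, tolerated skips included
    start_bp: int
    end_bp: int
    significant: bool = False
    traits: list = field(default_factory=list)

    @property
    def span_kbp(self) -> float:
        return round((self.end_bp - self.start_bp) / 1000.0, 2)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def pairwise_ld(dosages: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation between all dosage columns.

    Constant markers get r^2 = 0 with every other marker and 1 with
    themselves.  Input must be imputed (no missing values).
    """
    arr = dosages.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("dosages contain missing values; impute first")
    sd = arr.std(axis=0)
    const = sd == 0
    safe = arr.copy()
    safe[:, const] = 0.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(safe, rowvar=False)
    if np.ndim(c) == 0:  # single marker
        c = np.array([[1.0]])
    r2 = np.nan_to_num(c, nan=0.0) ** 2
    r2[const, :] = 0.0
    r2[:, const] = 0.0
    np.fill_diagonal(r2, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return pd.DataFrame(r2, index=dosages.columns, columns=dosages.columns)


def _blocks_one_chromosome(ld: np.ndarray, r2_min: float, tolerance: int) -> list[tuple[int, int]]:
    """Greedy seeding/extension on one chromosome; returns (first, last)
    member index spans in map order."""
    M = ld.shape[0]
    assigned = np.zeros(M, dtype=bool)
    spans = []
    while True:
        seed = -1
        best = -1.0
        for i in range(M - 1):
            if not assigned[i] and not assigned[i + 1] and ld[i, i + 1] > best:
                best = ld[i, i + 1]  # strict '>' keeps the leftmost tie
                seed = i
        if seed < 0 or best < r2_min:
            break
        left, right = seed, seed + 1  # conforming edges
        # rightward
        skips = 0
        j = right + 1
        while j < M and not assigned[j]:
            if ld[j, right] >= r2_min:
                right = j
                skips = 0
            else:
                skips += 1
                if skips > tolerance:
                    break
            j += 1
        # leftward
        skips = 0
        j = left - 1
        while j >= 0 and not assigned[j]:
            if ld[j, left] >= r2_min:
                left = j
                skips = 0
            else:
                skips += 1
                if skips > tolerance:
                    break
            j -= 1
        assigned[left:right + 1] = True
        spans.append((left, right))
    return sorted(spans)


def build_blocks(ld: pd.DataFrame, marker_map: pd.DataFrame,
                 r2_min: float = 0.4, tolerance: int = 12,
                 id_offset: int = 0) -> list[HaplotypeBlock]:
    """Blocks for the single chromosome covered by ``ld``.

    ``marker_map`` rows for these markers give bp positions; ids are
    ``b######`` counters starting after ``id_offset``.
    """
    markers = list(ld.index)
    pos = marker_map.loc[markers, "pos"].to_numpy()
    chroms = marker_map.loc[markers, "chromosome"].unique()
    if len(chroms) != 1:
        raise ValueError("build_blocks expects markers from a single chromosome")
    spans = _blocks_one_chromosome(ld.to_numpy(), r2_min, tolerance)
    out = []
    for k, (a, b) in enumerate(spans):
        out.append(HaplotypeBlock(
            id=f"b{id_offset + k + 1:06d}",
            chromosome=str(chroms[0]),
            markers=markers[a:b + 1],
            start_bp=int(pos[a]),
            end_bp=int(pos[b]),
        ))
    return out


def build_blocks_genome(dosages: pd.DataFrame, marker_map: pd.DataFrame,
                        r2_min: float = 0.4, tolerance: int = 12) -> list[HaplotypeBlock]:
    """Per-chromosome block construction over the whole map, with genome-wide
    sequential ids."""
    blocks = []
    for chrom in marker_map["chromosome"].unique():
        m = marker_map.index[marker_map["chromosome"] == chrom]
        ld = pairwise_ld(dosages[list(m)])
        blocks.extend(build_blocks(ld, marker_map, r2_min, tolerance, id_offset=len(blocks)))
    return blocks


def flag_blocks(blocks: list[HaplotypeBlock], gwas_table: pd.DataFrame,
                threshold: float = 1e-3):
    """Flag a block for a trait when any member marker is significant there.

    Returns ``(blocks, singletons)`` where ``singletons`` lists significant
    markers that fall in no block.
    """
    by_marker = {}
    for _, row in gwas_table[gwas_table["p"] <= threshold].iterrows():
        by_marker.setdefault(row["marker"], []).append((row["trait"], row["p"]))
    in_block = set()
    for b in blocks:
        traits = sorted({t for m in b.markers for t, _ in by_marker.get(m, [])})
        b.traits = traits
        b.significant = bool(traits)
        in_block.update(b.markers)
    singletons = gwas_table[(gwas_table["p"] <= threshold)
                            & ~gwas_table["marker"].isin(in_block)].copy()
    return blocks, singletons


def blocks_table(blocks: list[HaplotypeBlock], gwas_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flat TSV-ready table of blocks, with per-trait minimum member p."""
    rows = []
    for b in blocks:
        row = {"block": b.id, "chromosome": b.chromosome, "start_bp": b.start_bp,
               "end_bp": b.end_bp, "span_kbp": b.span_kbp, "n_markers": b.n_markers,
               "significant": b.significant, "traits": ";".join(b.traits)}
        if gwas_table is not None and len(gwas_table):
            sub = gwas_table[gwas_table["marker"].isin(b.markers)]
            for trait, grp in sub.groupby("trait"):
                row[f"min_p_{trait}"] = float(grp["p"].min())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class HaplotypeAllele:
    block: str
    label: str               # "1", "2", ... by descending carrier count; "rare"; "incomplete"
    pattern: tuple | None    # dosage pattern over member markers (None for pooled bins)
    carriers: list           # father line ids
    trait_stats: pd.DataFrame  # per trait: n, mean, median, q1, q3


def enumerate_alleles(block: HaplotypeBlock, dosages: pd.DataFrame,
                      values: pd.DataFrame, min_carriers: int = 3) -> list[HaplotypeAllele]:
    """Distinct multi-marker dosage patterns over the block's members.

    ``dosages`` must be the raw (non-imputed) father calls so that missing
    calls keep a line out of pattern assignment; such lines go to an
    "incomplete" bin.  Patterns with fewer than ``min_carriers`` carriers
    are pooled into "rare".  ``values`` carries a ``father`` column plus one
    column per trait (typically the hybrids' adjusted means); summaries are
    computed over all value rows whose father carries the pattern.
    """
    sub = dosages[block.markers]
    traits = [c for c in values.columns if c != "father"]

    patterns: dict[tuple, list] = {}
    incomplete = []
    for father, row in sub.iterrows():
        arr = row.to_numpy(dtype=float)
        if np.isnan(arr).any():
            incomplete.append(father)
        else:
            patterns.setdefault(tuple(arr.astype(int)), []).append(father)
    if not patterns:
        log.warning("block %s: every line has an incomplete pattern", block.id)
        return []

    common = {p: c for p, c in patterns.items() if len(c) >= min_carriers}
    rare_carriers = [f for p, c in patterns.items() if len(c) < min_carriers for f in c]
    ranked = sorted(common.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    def stats_for(carriers):
        rows = []
        vv = values[values["father"].isin(carriers)]
        for t in traits:
            x = vv[t].dropna()
            rows.append({"trait": t, "n": len(x), "mean": x.mean(), "median": x.median(),
                         "q1": x.quantile(0.25), "q3": x.quantile(0.75)})
        return pd.DataFrame(rows)

    out = []
    for k, (pat, carriers) in enumerate(ranked):
        out.append(HaplotypeAllele(block.id, str(k + 1), pat, sorted(carriers), stats_for(carriers)))
    if rare_carriers:
        out.append(HaplotypeAllele(block.id, "rare", None, sorted(rare_carriers), stats_for(rare_carriers)))
    if incomplete:
        out.append(HaplotypeAllele(block.id, "incomplete", None, sorted(incomplete), stats_for(incomplete)))
    return out


def allele_effect_range(alleles: list[HaplotypeAllele], trait: str) -> float:
    """Max minus min of the labelled (non-pooled) allele means for a trait."""
    means = []
    for a in alleles:
        if a.pattern is None:
            continue
        row = a.trait_stats[a.trait_stats["trait"] == trait]
        if len(row) and row["n"].iloc[0] > 0:
            means.append(float(row["mean"].iloc[0]))
    if len(means) < 2:
        return float("nan")
    return max(means) - min(means)


def alleles_table(alleles: list[HaplotypeAllele]) -> pd.DataFrame:
    rows = []
    for a in alleles:
        for _, s in a.trait_stats.iterrows():
            rows.append({"block": a.block, "allele": a.label,
                         "pattern": "" if a.pattern is None else "/".join(map(str, a.pattern)),
                         "n_carriers": len(a.carriers), "trait": s["trait"], "n_values": s["n"],
                         "mean": s["mean"], "median": s["median"], "q1": s["q1"], "q3": s["q3"]})
    return pd.DataFrame(rows)
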