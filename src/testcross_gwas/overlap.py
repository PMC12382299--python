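"""Stage 5: positional overlap of flagged blocks with literature QTL.

Literature QTL arrive as an already-positioned table (study, trait,
chromosome, bp) on the working reference; a QTL overlaps a block when its
position falls within the block's bp boundaries, both ends inclusive.
"""

from __future__ import annotations

import logging

import pandas as pd

from .blocks import HaplotypeBlock

log = logging.getLogger(__name__)

QTL_COLUMNS = ("study", "trait", "chromosome", "pos")


def read_qtl_table(path) -> pd.DataFrame:
    qtl = pd.read_csv(path, sep="\t")
    missing = set(QTL_COLUMNS) - set(qtl.columns)
    if missing:
        raise ValueError(f"QTL table lacks columns: {sorted(missing)}")
    if (qtl["pos"] < 0).any():
        raise ValueError("QTL positions must be >= 0")
    return qtl


def overlap(blocks: list[HaplotypeBlock], qtls: pd.DataFrame,
            significant_only: bool = True) -> pd.DataFrame:
    """(block, qtl) pairs with block.start_bp <= qtl.pos <= block.end_bp."""
    use = [b for b in blocks if b.significant] if significant_only else list(blocks)
    known_chroms = {b.chromosome for b in use}
    rows = []
    for _, q in qtls.iterrows():
        if q["chromosome"] not in known_chroms:
            log.warning("QTL %s/%s on chromosome %s: no blocks there, skipped",
                        q["study"], q["trait"], q["chromosome"])
            continue
        for b in use:
            if b.chromosome == q["chromosome"] and b.start_bp <= q["pos"] <= b.end_bp:
                rows.append({"block": b.id, "chromosome": b.chromosome,
                             "block_start_bp": b.start_bp, "block_end_bp": b.end_bp,
                             "block_traits": ";".join(b.traits),
                             "qtl_study": q["study"], "qtl_trait": q["trait"],
                             "qtl_pos": int(q["pos"])})
    return pd.DataFrame(rows, columns=["block", "chromosome", "block_start_bp",
                                       "block_end_bp", "block_traits",
                                       "qtl_study", "qtl_trait", "qtl_pos"])
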