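"""Marker quality control for homozygous-line dosage matrices.

Dosages are coded 0/1/2 copies of the counted (B) allele with ``NaN`` for
missing calls.  Lines are expected to be fully homozygous (doubled haploids),
so heterozygous calls (dosage 1) are treated as genotyping failures and set
missing before frequency-based filtering.  Both filter thresholds are
*inclusive* removals: a marker at minor allele frequency exactly 0.05 or at
a missing rate of exactly 5% is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MAP_COLUMNS = ("chromosome", "pos")


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix plus a physical marker map.

    ``dosages``: DataFrame indexed by individual id, one float column per
    marker (0/1/2, NaN = missing).  ``marker_map``: DataFrame indexed by
    marker id with columns ``chromosome`` and ``pos`` (bp), sorted by
    (chromosome, pos) and in the same order as the dosage columns.
    """

    dosages: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.is_unique:
            raise ValueError("individual ids must be unique")
        if not self.marker_map.index.is_unique:
            raise ValueError("marker ids must be unique")
        if list(self.dosages.columns) != list(self.marker_map.index):
            raise ValueError("dosage columns must match marker map order")
        m = self.marker_map
        if not m.sort_values(["chromosome", "pos"], kind="stable").index.equals(m.index):
            raise ValueError("marker map must be sorted by (chromosome, pos)")

    @property
    def ids(self) -> list:
        return list(self.dosages.index)

    @property
    def markers(self) -> list:
        return list(self.dosages.columns)

    def subset_markers(self, keep: list) -> "GenotypeMatrix":
        """Return a copy restricted to ``keep``, preserving map order."""
        keep = [m for m in self.marker_map.index if m in set(keep)]
        return GenotypeMatrix(self.dosages[keep].copy(), self.marker_map.loc[keep].copy())

    def write(self, dosage_path, map_path) -> None:
        self.dosages.to_csv(dosage_path, sep="\t", index_label="id")
        self.marker_map.to_csv(map_path, sep="\t", index_label="marker")

    @classmethod
    def read(cls, dosage_path, map_path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col="id")
        mp = pd.read_csv(map_path, sep="\t", index_col="marker")
        return cls(dos, mp[list(MAP_COLUMNS)])


@dataclass
class QCReport:
    """Per-rule accounting of the marker filtering.

    ``retained + removed_non_specific + removed_maf + removed_missing +
    removed_all_missing`` equals the input marker count.
    """

    n_input: int = 0
    het_set_missing: int = 0
    removed_non_specific: int = 0
    removed_maf: int = 0
    removed_missing: int = 0
    removed_all_missing: int = 0
    retained: int = 0
    removed_marker_ids: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("markers_input", self.n_input),
            ("het_calls_set_missing", self.het_set_missing),
            ("removed_non_specific", self.removed_non_specific),
            ("removed_maf", self.removed_maf),
            ("removed_missing_rate", self.removed_missing),
            ("removed_all_missing", self.removed_all_missing),
            ("markers_retained", self.retained),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def recode_het_to_missing(geno: GenotypeMatrix, report: QCReport | None = None) -> GenotypeMatrix:
    """Set every dosage-1 call missing; 0/2 calls are untouched."""
    dos = geno.dosages.copy()
    het = dos.to_numpy() == 1
    n_het = int(het.sum())
    if n_het:
        arr = dos.to_numpy(dtype=float, copy=True)
        arr[het] = np.nan
        dos = pd.DataFrame(arr, index=dos.index, columns=dos.columns)
    if report is not None:
        report.het_set_missing = n_het
    log.info("het-recode: %d heterozygous calls set missing", n_het)
    return GenotypeMatrix(dos, geno.marker_map.copy())


def apply_keep_list(geno: GenotypeMatrix, keep, report: QCReport | None = None) -> GenotypeMatrix:
    """Retain only markers on ``keep`` (a precomputed uniquely-placed list).

    Unknown ids in ``keep`` are warned about and ignored; an empty
    intersection is a hard error.
    """
    keep = set(keep)
    unknown = keep - set(geno.markers)
    if unknown:
        log.warning("keep-list: %d ids not in genotype matrix (ignored)", len(unknown))
    kept = [m for m in geno.markers if m in keep]
    if not kept:
        raise ValueError("keep list shares no markers with the genotype matrix")
    n_removed = len(geno.markers) - len(kept)
    if report is not None:
        report.removed_non_specific = n_removed
        report.removed_marker_ids["non_specific"] = [m for m in geno.markers if m not in keep]
    log.info("keep-list: removed %d markers, retained %d", n_removed, len(kept))
    return geno.subset_markers(kept)


def filter_maf_missing(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Discard markers with MAF <= ``maf_min`` or missing rate >= ``miss_max``.

    MAF is the frequency of the rarer allele among non-missing calls
    (dosages assumed het-recoded already).  Markers with every call missing
    are removed under the missingness rule but counted separately.
    """
    if report is None:
        report = QCReport(n_input=len(geno.markers))
    elif report.n_input == 0:
        report.n_input = len(geno.markers)

    arr = geno.dosages.to_numpy(dtype=float)
    n_ind = arr.shape[0]
    n_miss = np.isnan(arr).sum(axis=0)
    miss_rate = n_miss / n_ind
    n_called = n_ind - n_miss
    sums = np.nansum(arr, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, sums / np.maximum(n_called, 1), np.nan) / 2.0  # B-allele freq
    maf = np.minimum(p, 1.0 - p)

    all_missing = n_miss == n_ind
    drop_missing = (miss_rate >= miss_max) & ~all_missing
    drop_maf = np.zeros_like(drop_missing)
    ok = ~all_missing & ~drop_missing
    drop_maf[ok] = maf[ok] <= maf_min

    markers = np.asarray(geno.markers, dtype=object)
    report.removed_all_missing = int(all_missing.sum())
    report.removed_missing = int(drop_missing.sum())
    report.removed_maf = int(drop_maf.sum())
    report.removed_marker_ids["all_missing"] = list(markers[all_missing])
    report.removed_marker_ids["missing_rate"] = list(markers[drop_missing])
    report.removed_marker_ids["maf"] = list(markers[drop_maf])

    kept = list(markers[~(all_missing | drop_missing | drop_maf)])
    report.retained = len(kept)
    log.info(
        "maf/missing filter: removed %d (MAF), %d (missing), %d (all-missing); retained %d",
        report.removed_maf, report.removed_missing, report.removed_all_missing, report.retained,
    )
    if not kept:
        raise ValueError("no markers survive the MAF/missingness filter")
    return geno.subset_markers(kept), report


def impute_mean(geno: GenotypeMatrix) -> pd.DataFrame:
    """Replace missing calls with the marker's mean dosage.

    Returns the plain dosage DataFrame; the imputed matrix feeds the GRM,
    PCA and LD computations only — haplotype-allele enumeration works on the
    raw (non-imputed) calls so that incomplete patterns stay identifiable.
    """
    arr = geno.dosages.to_numpy(dtype=float, copy=True)
    means = np.nanmean(arr, axis=0)
    idx = np.where(np.isnan(arr))
    arr[idx] = means[idx[1]]
    return pd.DataFrame(arr, index=geno.dosages.index, columns=geno.dosages.columns)


def run_qc(
    geno: GenotypeMatrix,
    keep=None,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC chain: optional keep-list, het recode, MAF/missingness filter."""
    report = QCReport(n_input=len(geno.markers))
    if keep is not None:
        geno = apply_keep_list(geno, keep, report)
    geno = recode_het_to_missing(geno, report)
    geno, report = filter_maf_missing(geno, maf_min, miss_max, report)
    return geno, report
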