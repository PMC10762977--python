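"""Bin grids, count matrices and on-disk formats.

All genomic coordinates are 0-based, half-open, both internally and in the
BED-like segment output.  Count matrices are TSV: one header row of bin
labels ``chrom:start-end`` and a first column ``cell_id``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class BinGrid:
    """Consecutive equal-sized genomic bins with GC and mappability tracks.

    Parameters
    ----------
    chroms, starts, ends
        Per-bin coordinates, sorted by (chrom, start), non-overlapping.
        ``end - start == bin_size`` except possibly for the last bin of a
        chromosome.
    gc, mappability
        Per-bin fractions in [0, 1].
    bin_size
        Nominal bin width in bp.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray
    bin_size: int

    def __post_init__(self):
        n = len(self.chroms)
        for name in ("starts", "ends", "gc", "mappability"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValidationError("gc outside [0, 1]")
        if np.any((self.mappability < 0) | (self.mappability > 1)):
            raise ValidationError("mappability outside [0, 1]")
        # sorted, non-overlapping within chromosome
        for chrom in pd.unique(self.chroms):
            m = self.chroms == chrom
            s, e = self.starts[m], self.ends[m]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise ValidationError(f"bins on {chrom} unsorted or overlapping")

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    def labels(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]

    def chrom_boundaries(self) -> np.ndarray:
        """Bin indices where a new chromosome starts (excluding index 0)."""
        change = np.nonzero(self.chroms[1:] != self.chroms[:-1])[0] + 1
        return change.astype(int)

    def subset(self, keep: np.ndarray) -> "BinGrid":
        return BinGrid(
            self.chroms[keep], self.starts[keep], self.ends[keep],
            self.gc[keep], self.mappability[keep], self.bin_size,
        )


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Raw per-cell per-bin read counts (N cells x M bins)."""

    counts: np.ndarray
    cell_ids: list[str]
    bingrid: BinGrid

    def __post_init__(self):
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (cells x bins)")
        n, m = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(set(self.cell_ids)) != n:
            dup = [c for c in self.cell_ids if self.cell_ids.count(c) > 1][0]
            raise ValidationError(f"duplicate cell id {dup!r}")
        if m != self.bingrid.n_bins:
            raise ValidationError(f"{m} count columns vs {self.bingrid.n_bins} bins")
        if np.any(self.counts < 0):
            i, k = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count at cell {self.cell_ids[i]!r}, bin {k}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# bin tables

def write_bingrid(bg: BinGrid, path) -> None:
    pd.DataFrame({
        "chrom": bg.chroms, "start": bg.starts, "end": bg.ends,
        "gc": bg.gc, "mappability": bg.mappability,
    }).to_csv(path, sep="\t", index=False)


def load_bingrid(path) -> BinGrid:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gc", "mappability"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"bin table missing columns {sorted(missing)}")
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.bincount(widths).argmax()) if len(widths) else 0
    return BinGrid(
        df["chrom"].to_numpy(), df["start"].to_numpy().astype(int),
        df["end"].to_numpy().astype(int), df["gc"].to_numpy(float),
        df["mappability"].to_numpy(float), bin_size,
    )


# ---------------------------------------------------------------------------
# count matrices

def write_count_matrix(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.cell_ids, name="cell_id"),
                      columns=cm.bingrid.labels())
    df.to_csv(path, sep="\t")


def load_count_matrix(path, bingrid_path) -> CountMatrix:
    bg = load_bingrid(bingrid_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != bg.labels():
        raise ValidationError("count matrix header does not match bin table bins")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError("non-numeric entries in count matrix")
    if np.any(counts != np.floor(counts)):
        raise ValidationError("non-integer counts")
    return CountMatrix(counts.astype(np.int64), [str(c) for c in df.index], bg)


def write_real_matrix(values: np.ndarray, cell_ids: Sequence[str],
                      labels: Sequence[str], path) -> None:
    """Write a float matrix (e.g. LRC) at full double precision."""
    pd.DataFrame(values, index=pd.Index(list(cell_ids), name="cell_id"),
                 columns=list(labels)).to_csv(path, sep="\t", float_format="%.10g")


def load_real_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns]


# ---------------------------------------------------------------------------
# alignment extraction

def extract_counts_from_alignments(
    alignment_paths,
    bingrid: BinGrid,
    *,
    barcodes: Sequence[str] | None = None,
    barcode_tag: str = "CB",
    min_mapq: int = 0,
) -> CountMatrix:
    """Count read alignments per cell per bin from BAM/SAM files.

    Two modes: a list of per-cell files (one row per file, cell id = file
    stem), or a single merged file plus ``barcodes``, where each read's cell
    is read from ``barcode_tag``.  A read is assigned to exactly one bin by
    its leftmost aligned position; unmapped, secondary, supplementary and
    duplicate records are excluded.  Cells with zero reads are retained.
    """
    import pysam

    if barcodes is not None:
        if not barcodes:
            raise ValueError("merged mode requires a non-empty barcode list")
        if isinstance(alignment_paths, (str, bytes)) or not isinstance(alignment_paths, (list, tuple)):
            paths = [alignment_paths]
        else:
            paths = list(alignment_paths)
        if len(paths) != 1:
            raise ValueError("merged mode takes exactly one alignment file")
        cell_ids = [str(b) for b in barcodes]
        row_of = {b: i for i, b in enumerate(cell_ids)}
        counts = np.zeros((len(cell_ids), bingrid.n_bins), dtype=np.int64)
        with pysam.AlignmentFile(str(paths[0]), check_sq=False) as bam:
            for read in bam.fetch(until_eof=True):
                if _excluded(read, min_mapq):
                    continue
                if not read.has_tag(barcode_tag):
                    continue
                row = row_of.get(read.get_tag(barcode_tag))
                if row is None:
                    continue
                k = _bin_of(bingrid, read.reference_name, read.reference_start)
                if k is not None:
                    counts[row, k] += 1
        return CountMatrix(counts, cell_ids, bingrid)

    paths = list(alignment_paths)
    cell_ids = [_stem(p) for p in paths]
    counts = np.zeros((len(paths), bingrid.n_bins), dtype=np.int64)
    for i, p in enumerate(paths):
        with pysam.AlignmentFile(str(p), check_sq=False) as bam:
            for read in bam.fetch(until_eof=True):
                if _excluded(read, min_mapq):
                    continue
                k = _bin_of(bingrid, read.reference_name, read.reference_start)
                if k is not None:
                    counts[i, k] += 1
    return CountMatrix(counts, cell_ids, bingrid)


def _excluded(read, min_mapq: int) -> bool:
    return (read.is_unmapped or read.is_secondary or read.is_supplementary
            or read.is_duplicate or read.mapping_quality < min_mapq)


def _bin_of(bg: BinGrid, chrom: str | None, pos: int):
    if chrom is None:
        return None
    m = np.nonzero((bg.chroms == chrom) & (bg.starts <= pos) & (pos < bg.ends))[0]
    return int(m[0]) if len(m) else None


def _stem(path) -> str:
    import os
    base = os.path.basename(str(path))
    for suffix in (".bam", ".sam", ".cram"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return base


# ---------------------------------------------------------------------------
# segment output

def write_segments(segmentation, bingrid: BinGrid, path) -> None:
    """BED-like table: chrom, start (0-based), end (exclusive), segment index."""
    rows = []
    for idx, (lo, hi) in enumerate(segmentation.bounds()):
        rows.append((bingrid.chroms[lo], int(bingrid.starts[lo]),
                     int(bingrid.ends[hi - 1]), idx))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "segment"]).to_csv(
        path, sep="\t", index=False, header=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "segment"], dtype={"chrom": str})
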