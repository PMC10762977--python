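"""Quality filters and normalizations producing the log2 read-count matrix.

The fixed pipeline order is: GC/mappability track filter, per-cell library
size normalization, extreme-bin (quantile) filter, per-cell Gini filter,
per-cell median normalization against GC then mappability strata, and
finally log2 transform.  The working signal downstream is the N x M matrix
of log2 read counts (LRC), where for a region at copy number c in a cell of
ploidy p the expected LRC is log2(0.5 c) - log2(0.5 p) around a cell-level
baseline.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io_counts import BinGrid, CountMatrix

#: floor applied to corrected counts before log2.  Chosen as 0.125 so a
#: zero-count bin maps to LRC log2(0.125) = -3, the mean the copy-number-0
#: mixture state expects (its pseudo copy number is 0.25): floored bins then
#: sit on that state instead of acting as -13 outliers that inflate sigma.
LRC_FLOOR = 0.125


@dataclasses.dataclass
class QCReport:
    """Record of every bin/cell removed during preprocessing and the factors used."""

    removed_bins: list = dataclasses.field(default_factory=list)   # (bin index, reason)
    removed_cells: list = dataclasses.field(default_factory=list)  # (cell id, gini)
    library_factors: dict = dataclasses.field(default_factory=dict)

    def to_lines(self) -> list[str]:
        lines = [f"bin\t{idx}\t{reason}" for idx, reason in self.removed_bins]
        lines += [f"cell\t{cid}\tgini={g:.4f}" for cid, g in self.removed_cells]
        return lines


@dataclasses.dataclass(frozen=True)
class LRCMatrix:
    """Filtered, normalized log2 read counts (the matrix X)."""

    lrc: np.ndarray
    cell_ids: list[str]
    bingrid: BinGrid

    def __post_init__(self):
        if not np.all(np.isfinite(self.lrc)):
            raise ValueError("non-finite LRC entries")
        n, m = self.lrc.shape
        if n < 1 or m < 2:
            raise ValueError(f"LRC matrix too small: {n} x {m}")
        if m != self.bingrid.n_bins:
            raise ValueError("LRC columns do not match bin grid")

    @property
    def n_cells(self) -> int:
        return self.lrc.shape[0]

    @property
    def n_bins(self) -> int:
        return self.lrc.shape[1]


def filter_bins_by_tracks(cm: CountMatrix, *, gc_low: float = 0.10,
                          gc_high: float = 0.90, map_min: float = 0.90,
                          report: QCReport | None = None):
    """Drop bins with extreme GC content or low mappability.

    Each removed bin is logged with the single reason that triggered it
    (gc_low, gc_high, mappability — checked in that order).
    """
    report = report if report is not None else QCReport()
    bg = cm.bingrid
    keep = np.ones(bg.n_bins, dtype=bool)
    for k in range(bg.n_bins):
        if bg.gc[k] < gc_low:
            report.removed_bins.append((k, "gc_low"))
        elif bg.gc[k] > gc_high:
            report.removed_bins.append((k, "gc_high"))
        elif bg.mappability[k] < map_min:
            report.removed_bins.append((k, "mappability"))
        else:
            continue
        keep[k] = False
    if not keep.any():
        raise ValueError("no bins survive track filters")
    out = CountMatrix(cm.counts[:, keep], cm.cell_ids, bg.subset(keep))
    return out, report


def library_size_normalize(counts: np.ndarray, cell_ids,
                           report: QCReport | None = None) -> np.ndarray:
    """Divide each cell's counts by its own mean count; row means become 1."""
    means = counts.mean(axis=1)
    zero = np.nonzero(means <= 0)[0]
    if len(zero):
        raise ValueError(f"cell {cell_ids[zero[0]]!r} has zero mean count")
    if report is not None:
        report.library_factors = {c: float(m) for c, m in zip(cell_ids, means)}
    return counts / means[:, None]


def filter_extreme_bins(norm: np.ndarray, bingrid: BinGrid, *, q: float = 0.01,
                        report: QCReport | None = None):
    """Drop bins whose across-cell mean falls in the lower/upper q quantile.

    Quantiles use linear interpolation; bins exactly at a boundary are kept,
    so a degenerate all-equal input removes nothing.
    """
    if norm.shape[1] < 3:
        raise ValueError("need at least 3 bins for the quantile filter")
    if q <= 0:
        return norm, bingrid, (report if report is not None else QCReport())
    report = report if report is not None else QCReport()
    means = norm.mean(axis=0)
    lo, hi = np.quantile(means, [q, 1.0 - q])
    keep = (means >= lo) & (means <= hi)
    for k in np.nonzero(~keep)[0]:
        report.removed_bins.append((int(k), "quantile"))
    return norm[:, keep], bingrid.subset(keep), report


def gini_coefficient(row: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector, mean-absolute-difference form.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); 0 for perfect equality,
    approaching 1 as reads concentrate in one bin.  Scale-invariant.
    """
    x = np.asarray(row, dtype=float)
    if x.size < 2:
        raise ValueError("Gini needs at least 2 entries")
    if np.any(x < 0):
        raise ValueError("Gini defined for non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for all-zero row")
    xs = np.sort(x)
    n = x.size
    # sum_ij |x_i - x_j| = 2 * sum_i (2i - n + 1) x_(i), i 0-based ascending
    pair_sum = 2.0 * np.sum((2 * np.arange(n) - n + 1) * xs)
    return float(pair_sum / (2.0 * n * total))


def filter_cells_by_gini(norm: np.ndarray, cell_ids, raw_counts: np.ndarray,
                         *, threshold: float = 0.3,
                         report: QCReport | None = None):
    """Drop cells whose raw-count Gini coefficient is >= threshold."""
    report = report if report is not None else QCReport()
    ginis = np.array([gini_coefficient(r) for r in raw_counts])
    keep = ginis < threshold
    for i in np.nonzero(~keep)[0]:
        report.removed_cells.append((cell_ids[i], float(ginis[i])))
    if not keep.any():
        raise ValueError("no cells survive Gini filter")
    return norm[keep], [c for c, k in zip(cell_ids, keep) if k], report


def _strata(values: np.ndarray, width: float) -> np.ndarray:
    return np.floor(np.clip(values, 0.0, 1.0 - 1e-12) / width).astype(int)


def _median_correct(mat: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Per cell: r_hat_k = r_k * m / m_k with m the cell median over all bins,
    m_k the cell median over bins in bin k's stratum."""
    out = np.empty_like(mat, dtype=float)
    for i, row in enumerate(mat):
        m = np.median(row)
        corrected = row.copy().astype(float)
        for s in np.unique(strata):
            mask = strata == s
            mk = np.median(row[mask])
            if mk <= 0:
                warnings.warn(f"stratum {s} has non-positive median; using global median")
                mk = m if m > 0 else 1.0
            corrected[mask] = row[mask] * (m / mk)
        out[i] = corrected
    return out


def median_normalize(norm: np.ndarray, bingrid: BinGrid, *,
                     gc_width: float = 0.01, map_width: float = 0.02) -> np.ndarray:
    """Median normalization against GC strata, then mappability strata.

    Strata are equal-width value bins over [0, 1] (GC width 0.01,
    mappability width 0.02 by default); correction is applied per cell.
    """
    corrected = _median_correct(norm, _strata(bingrid.gc, gc_width))
    corrected = _median_correct(corrected, _strata(bingrid.mappability, map_width))
    return corrected


def to_lrc(corrected: np.ndarray, cell_ids, bingrid: BinGrid,
           *, floor: float = LRC_FLOOR,
           raw_counts: np.ndarray | None = None) -> LRCMatrix:
    """log2 transform with a small positive floor to keep zeros finite.

    When the raw counts are supplied, the first-order Jensen bias of the
    log of a counting variable, E[log2 X] = log2 E[X] - 1/(2 E[X] ln 2),
    is removed with the plug-in term 1/(2 x ln 2) per bin.  Without the
    correction, segments at low copy number sit systematically below
    log2 of their copy ratio, a displacement that accumulates over long
    segments and biases the downstream baseline-shift fit.
    """
    lrc = np.log2(np.maximum(corrected, floor))
    if raw_counts is not None:
        with np.errstate(divide="ignore"):
            debias = 1.0 / (2.0 * np.log(2.0) * np.maximum(raw_counts, 1))
        lrc = lrc + np.where(raw_counts > 0, debias, 0.0)
    return LRCMatrix(lrc, list(cell_ids), bingrid)


def preprocess(cm: CountMatrix, *, gc_low: float = 0.10, gc_high: float = 0.90,
               map_min: float = 0.90, quantile: float = 0.01,
               gini_max: float = 0.3, gc_width: float = 0.01,
               map_width: float = 0.02) -> tuple[LRCMatrix, QCReport]:
    """Run the full preprocessing pipeline in its fixed order."""
    report = QCReport()
    filtered, report = filter_bins_by_tracks(
        cm, gc_low=gc_low, gc_high=gc_high, map_min=map_min, report=report)
    norm = library_size_normalize(filtered.counts, filtered.cell_ids, report)
    n_removed_before = len(report.removed_bins)
    norm, bg, report = filter_extreme_bins(norm, filtered.bingrid, q=quantile,
                                           report=report)
    # Gini on the raw counts of the surviving bins, one value per cell
    dropped = {idx for idx, _ in report.removed_bins[n_removed_before:]}
    keep_cols = np.array([k not in dropped for k in range(filtered.n_bins)])
    norm, cell_ids, report = filter_cells_by_gini(
        norm, filtered.cell_ids, filtered.counts[:, keep_cols],
        threshold=gini_max, report=report)
    corrected = median_normalize(norm, bg, gc_width=gc_width, map_width=map_width)
    kept_rows = np.array([c in set(cell_ids) for c in filtered.cell_ids])
    raw_kept = filtered.counts[np.ix_(kept_rows, keep_cols)]
    return to_lrc(corrected, cell_ids, bg, raw_counts=raw_kept), report
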