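"""Metrics comparing inferred copy number profiles against ground truth.

Four metrics: summed nearest-neighbor breakpoint distance (bin units),
the over-segmentation ratio w = |inferred| / |true| breakpoints, per-cell
mean absolute difference (MAD) of copy numbers over common bins, and
per-cell average copy number (ACN) with its truth-minus-inferred delta.
"""

from __future__ import annotations

import dataclasses

import numpy as np


def breakpoint_distance(real_bps, inferred_bps, *, n_bins: int | None = None) -> int:
    """Sum over real breakpoints of the distance to the nearest inferred one.

    If no breakpoints were inferred, each real breakpoint contributes the
    full bin count (a documented worst-case convention), which requires
    ``n_bins``.
    """
    real = np.sort(np.asarray(list(real_bps), dtype=int))
    inferred = np.sort(np.asarray(list(inferred_bps), dtype=int))
    if real.size == 0:
        raise ValueError("breakpoint distance undefined for an empty real set")
    if inferred.size == 0:
        if n_bins is None:
            raise ValueError("n_bins required when no breakpoints were inferred")
        return int(real.size * n_bins)
    d = np.abs(real[:, None] - inferred[None, :]).min(axis=1)
    return int(d.sum())


def breakpoint_ratio_w(real_bps, inferred_bps) -> float:
    """w = number of inferred breakpoints / number of real breakpoints."""
    n_real = len(list(real_bps))
    if n_real == 0:
        raise ValueError("w undefined for an empty real set")
    return len(list(inferred_bps)) / n_real


def mad_per_cell(true_cn: np.ndarray, inferred_cn: np.ndarray,
                 common_bins: np.ndarray | None = None) -> float:
    """Mean |true - inferred| copy number over the common bins of one cell."""
    t = np.asarray(true_cn, dtype=float)
    i = np.asarray(inferred_cn, dtype=float)
    if common_bins is not None:
        common_bins = np.asarray(common_bins)
        if common_bins.size == 0:
            raise ValueError("common bin set is empty")
        t, i = t[common_bins], i[common_bins]
    if t.shape != i.shape:
        raise ValueError("profiles have different lengths")
    return float(np.mean(np.abs(t - i)))


def acn_delta(true_cn: np.ndarray, inferred_cn: np.ndarray) -> tuple[float, float, float]:
    """(ACN_true, ACN_inferred, delta = true - inferred) for one cell."""
    acn_t = float(np.mean(true_cn))
    acn_i = float(np.mean(inferred_cn))
    return acn_t, acn_i, acn_t - acn_i


@dataclasses.dataclass
class EvalReport:
    """All four metrics for one dataset."""

    breakpoint_distance: int
    w: float
    mad: np.ndarray            # per cell
    acn_true: np.ndarray
    acn_inferred: np.ndarray

    @property
    def mean_mad(self) -> float:
        return float(np.mean(self.mad))

    @property
    def delta_acn(self) -> np.ndarray:
        return self.acn_true - self.acn_inferred

    @property
    def median_delta_acn(self) -> float:
        return float(np.median(self.delta_acn))

    def to_dict(self) -> dict:
        return {
            "breakpoint_distance": self.breakpoint_distance,
            "w": self.w,
            "mean_mad": self.mean_mad,
            "median_delta_acn": self.median_delta_acn,
        }


def evaluate_profiles(true_cn: np.ndarray, inferred_cn: np.ndarray,
                      real_bps, inferred_bps, *,
                      common_bins: np.ndarray | None = None) -> EvalReport:
    """Compute every metric for matched cell orderings of truth and inference."""
    if true_cn.shape[0] != inferred_cn.shape[0]:
        raise ValueError("cell counts differ between truth and inference")
    mads = np.array([mad_per_cell(t, i, common_bins)
                     for t, i in zip(true_cn, inferred_cn)])
    if common_bins is not None:
        true_cn = true_cn[:, common_bins]
        inferred_cn = inferred_cn[:, common_bins]
    return EvalReport(
        breakpoint_distance=breakpoint_distance(
            real_bps, inferred_bps, n_bins=true_cn.shape[1]),
        w=breakpoint_ratio_w(real_bps, inferred_bps),
        mad=mads,
        acn_true=true_cn.mean(axis=1),
        acn_inferred=inferred_cn.mean(axis=1),
    )


def common_bin_indices(*label_lists) -> list[np.ndarray]:
    """Index arrays selecting the bins shared by every labeled profile set."""
    common = set(label_lists[0])
    for labels in label_lists[1:]:
        common &= set(labels)
    return [np.array([k for k, lab in enumerate(labels) if lab in common])
            for labels in label_lists]
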