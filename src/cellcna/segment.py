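"""Circular binary segmentation of latent bin sequences.

Breakpoints are detected independently along each latent dimension, per
chromosome, with the canonical circular binary segmentation recursion: at
each stage the pair of circular split points maximizing the between-arc
t-like statistic is located exhaustively, its significance is assessed by
a seeded permutation test, and accepted splits are recursed into until no
further split passes.  Breakpoint sets from all latent rows are merged by
union.  A breakpoint at b means a new segment starts at bin b, i.e. it
separates bins [.., b-1] and [b, ..].
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class BreakpointSet:
    """Sorted bin indices in (0, M) at which a new segment starts."""

    positions: tuple
    n_bins: int

    def __post_init__(self):
        pos = tuple(sorted(int(p) for p in set(self.positions)))
        object.__setattr__(self, "positions", pos)
        if pos and (pos[0] <= 0 or pos[-1] >= self.n_bins):
            raise ValueError("breakpoints must lie strictly inside (0, M)")

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(self.positions)


@dataclasses.dataclass(frozen=True)
class Segmentation:
    """Partition of M bins into K contiguous segments."""

    breakpoints: BreakpointSet
    n_bins: int

    @property
    def K(self) -> int:
        return len(self.breakpoints) + 1

    @property
    def lengths(self) -> np.ndarray:
        edges = [0, *self.breakpoints, self.n_bins]
        return np.diff(edges)

    def bounds(self) -> list[tuple[int, int]]:
        edges = [0, *self.breakpoints, self.n_bins]
        return list(zip(edges[:-1], edges[1:]))

    def bin_to_segment(self) -> np.ndarray:
        """Length-M vector mapping each bin to its segment index."""
        out = np.empty(self.n_bins, dtype=int)
        for k, (lo, hi) in enumerate(self.bounds()):
            out[lo:hi] = k
        return out


def _arc_stats(x: np.ndarray):
    """Max circular split statistic and its (i, j) location, exhaustively.

    For every arc x[i:j] vs its complement the statistic is
    |mean_arc - mean_rest| / sqrt(1/k + 1/(m-k)); the residual-scale factor
    is constant under permutation and therefore omitted.
    """
    m = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[m]
    idx = np.arange(m + 1)
    K = idx[None, :] - idx[:, None]          # arc length j - i
    SA = S[None, :] - S[:, None]             # arc sum
    valid = (K >= 1) & (K <= m - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = SA / K - (total - SA) / (m - K)
        T = np.abs(diff) / np.sqrt(1.0 / K + 1.0 / (m - K))
    T[~valid] = -np.inf
    flat = int(np.argmax(T))
    i, j = divmod(flat, m + 1)
    return float(T[i, j]), i, j


def _max_stat_only(x: np.ndarray) -> float:
    return _arc_stats(x)[0]


def _binary_split_pvalue(x: np.ndarray, rng, n_permutations: int) -> float:
    """Permutation p-value of the best single (non-circular) split of x."""
    n = len(x)
    if n < 2 or np.ptp(x) == 0.0:
        return 1.0
    S = np.concatenate(([0.0], np.cumsum(x)))
    k = np.arange(1, n)

    def max_t(s):
        cs = np.concatenate(([0.0], np.cumsum(s)))
        diff = cs[1:n] / k - (cs[n] - cs[1:n]) / (n - k)
        return float(np.max(np.abs(diff) / np.sqrt(1.0 / k + 1.0 / (n - k))))

    t_obs = max_t(x)
    exceed = sum(max_t(rng.permutation(x)) >= t_obs for _ in range(n_permutations))
    return (1.0 + exceed) / (1.0 + n_permutations)


def cbs_segment(sequence: Sequence[float], *, alpha: float = 0.1,
                n_permutations: int = 1000, seed: int = 0,
                validate: bool = True) -> BreakpointSet:
    """Recursive CBS on one sequence; returns breakpoints in linear coordinates.

    A candidate split is accepted when its permutation p-value
    (1 + #{perm max >= observed}) / (1 + n_permutations) is below ``alpha``.
    With ``validate`` (the canonical change-point validation pass), each
    detected breakpoint is re-tested as a single split of the region between
    its neighboring breakpoints and removed when no longer significant,
    repeating until the set is stable; this prunes spurious splits accepted
    against a wider background during the recursion.
    """
    x = np.asarray(sequence, dtype=float)
    m = len(x)
    if m < 2:
        return BreakpointSet((), max(m, 1))
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    found: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 or np.ptp(seg) == 0.0:
            return
        t_obs, i, j = _arc_stats(seg)
        exceed = 0
        for _ in range(n_permutations):
            if _max_stat_only(rng.permutation(seg)) >= t_obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_permutations)
        if p >= alpha:
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        if not cuts:
            return
        found.extend(lo + c for c in cuts)
        edges = [0, *cuts, n]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(lo + a, lo + b)

    recurse(0, m)
    bps = sorted(set(found))
    if validate:
        while bps:
            edges = [0, *bps, m]
            pvals = [_binary_split_pvalue(x[edges[t]:edges[t + 2]], rng,
                                          n_permutations)
                     for t in range(len(bps))]
            worst = int(np.argmax(pvals))
            if pvals[worst] < alpha:
                break
            bps.pop(worst)
    return BreakpointSet(tuple(bps), m)


def merge_breakpoints(sets: Iterable[BreakpointSet], n_bins: int | None = None) -> BreakpointSet:
    """Union of breakpoint sets sharing one bin coordinate space."""
    sets = list(sets)
    if n_bins is None:
        if not sets:
            raise ValueError("n_bins required for an empty list of sets")
        n_bins = sets[0].n_bins
    if any(s.n_bins != n_bins for s in sets):
        raise ValueError("breakpoint sets refer to different bin counts")
    merged: set[int] = set()
    for s in sets:
        merged.update(s.positions)
    return BreakpointSet(tuple(merged), n_bins)


def segmentation_from_breakpoints(bps: BreakpointSet, n_bins: int,
                                  chrom_boundaries: Sequence[int] = ()) -> Segmentation:
    """Build a Segmentation; chromosome starts are always breakpoints."""
    pos = set(bps.positions)
    for b in chrom_boundaries:
        if not 0 < b < n_bins:
            raise IndexError(f"chromosome boundary {b} outside (0, {n_bins})")
        pos.add(int(b))
    if pos and max(pos) >= n_bins:
        raise IndexError("breakpoint beyond bin count")
    return Segmentation(BreakpointSet(tuple(pos), n_bins), n_bins)


def segment_latent(z: np.ndarray, chrom_boundaries: Sequence[int], n_bins: int,
                   *, alpha: float = 0.1, n_permutations: int = 1000,
                   seed: int = 0) -> BreakpointSet:
    """Run CBS on each latent row within each chromosome and merge the results."""
    z = np.atleast_2d(z)
    if z.shape[1] != n_bins:
        raise ValueError("latent matrix columns do not match bin count")
    edges = [0, *sorted(chrom_boundaries), n_bins]
    all_bps: set[int] = set()
    for d, row in enumerate(z):
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = cbs_segment(row[lo:hi], alpha=alpha,
                              n_permutations=n_permutations,
                              seed=seed + 7919 * d + lo)
            all_bps.update(lo + b for b in sub)
    return BreakpointSet(tuple(all_bps), n_bins)
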