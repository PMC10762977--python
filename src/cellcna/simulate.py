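"""Ground-truthed synthetic scDNA-seq bin counts from a clonal tree.

The generator emulates low-coverage tumor scDNA-seq at the bin-count
level.  A random clonal tree is grown from an ancestral clone at uniform
ploidy (2, 3 or 4); each edge carries one or more CNA events with lengths
uniform in 3-20 Mb and copy change in {-2, -1, +1, +2} (clipped at zero).
Cells are assigned to clones (plus an optional fraction of ploidy-2
normal cells) and their per-bin counts are drawn negative-binomially with

    mean = depth_mean * c / ploidy * g(gc)

where c is the cell's true copy number in the bin, depth_mean the expected
reads per bin at the baseline ploidy (40 by default, the regime of 0.02x
coverage with 200 kb bins and ~100 bp reads), and g an optional GC bias
curve.  The dispersion parameter models WGA overdispersion.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Sequence

import numpy as np

from .io_counts import BinGrid, CountMatrix

#: default genome for simulations: chromosome name -> length (bp)
DEFAULT_GENOME = {f"chr{i}": 30_000_000 for i in range(1, 9)}


def make_bingrid(genome: dict[str, int] | None = None, *, bin_size: int = 200_000,
                 gc: float | np.ndarray = 0.45, mappability: float | np.ndarray = 1.0,
                 seed: int | None = None, gc_sd: float = 0.0) -> BinGrid:
    """Tile a genome into fixed-width bins with flat or jittered tracks."""
    genome = dict(genome) if genome else dict(DEFAULT_GENOME)
    chroms, starts, ends = [], [], []
    for chrom, length in genome.items():
        for s in range(0, length, bin_size):
            chroms.append(chrom)
            starts.append(s)
            ends.append(min(s + bin_size, length))
    n = len(chroms)
    gc_arr = np.broadcast_to(np.asarray(gc, float), (n,)).copy()
    if gc_sd > 0:
        rng = np.random.default_rng(seed)
        gc_arr = np.clip(gc_arr + rng.normal(0.0, gc_sd, n), 0.0, 1.0)
    map_arr = np.broadcast_to(np.asarray(mappability, float), (n,)).copy()
    return BinGrid(np.array(chroms), np.array(starts), np.array(ends),
                   gc_arr, map_arr, bin_size)


@dataclasses.dataclass
class CNAEvent:
    chrom: str
    start: int        # bp, 0-based
    end: int          # bp, exclusive
    change: int       # copy change, in {-2, -1, +1, +2}


@dataclasses.dataclass
class ClonalTree:
    """Tumor clones with integer CN profiles over a bin grid.

    Row 0 of ``profiles`` is the ancestral state (uniform at the tree's
    ploidy); rows 1..n_clones are the sampled tumor clones, each carrying
    the CNA events of its edge on top of its parent's profile.
    """

    bingrid: BinGrid
    ploidy: int
    profiles: np.ndarray        # (n_clones + 1) x M integer copy numbers
    parents: list[int]          # parent index per node, -1 for the root
    events: list[list[CNAEvent]]
    fractions: np.ndarray       # cell-fractions of the sampled clones

    @property
    def n_clones(self) -> int:
        """Number of sampled tumor clones (the root state is not sampled)."""
        return self.profiles.shape[0] - 1

    @property
    def clone_profiles(self) -> np.ndarray:
        return self.profiles[1:]


def _reducible(profile: np.ndarray, ploidy: int) -> bool:
    """True if the profile admits an exact lower-baseline reinterpretation.

    A cell whose copy numbers are all divisible so that c * b / ploidy is
    integer for some baseline b < ploidy is unidentifiable from normalized
    read counts (the baseline shift absorbs any uniform rescaling), so such
    clone profiles are rejected during simulation.
    """
    for b in range(1, ploidy):
        if np.all((profile * b) % ploidy == 0):
            return True
    return False


def simulate_tree(n_clones: int = 4, *, ploidy: int = 2,
                  bingrid: BinGrid | None = None,
                  cna_size_range: tuple[int, int] = (3_000_000, 20_000_000),
                  events_per_edge: tuple[int, int] = (1, 3),
                  seed: int = 0, max_tries: int = 100) -> ClonalTree:
    """Grow a random clonal tree from a uniform ancestral state.

    Each of the ``n_clones`` sampled clones hangs off a random existing
    node with 1-3 CNA events (lengths uniform in ``cna_size_range``, copy
    change in {-2, -1, +1, +2}, clipped at zero).  Clones whose profile is
    an exact multiple of a lower baseline (and would therefore have an
    unidentifiable ploidy) are resampled; with ``events_per_edge=(0, 0)``
    clones simply copy their parent and the check is skipped.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if ploidy not in (2, 3, 4):
        raise ValueError("ploidy must be 2, 3 or 4")
    bg = bingrid if bingrid is not None else make_bingrid()
    rng = np.random.default_rng(seed)
    M = bg.n_bins
    profiles = [np.full(M, ploidy, dtype=int)]
    parents = [-1]
    events: list[list[CNAEvent]] = [[]]
    chrom_names = list(dict.fromkeys(bg.chroms))
    chrom_len = {c: int(bg.ends[bg.chroms == c].max()) for c in chrom_names}

    def draw_event(child: np.ndarray):
        for _ in range(max_tries):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            size = int(rng.uniform(*cna_size_range))
            if size >= chrom_len[chrom]:
                continue
            start = int(rng.integers(0, chrom_len[chrom] - size))
            end = start + size
            change = int(rng.choice([-2, -1, 1, 2]))
            mask = (bg.chroms == chrom) & (bg.starts < end) & (bg.ends > start)
            if mask.any() and np.all(child[mask] + change >= 0):
                child[mask] += change
                return CNAEvent(chrom, start, end, change)
        raise RuntimeError("could not place CNA event (genome exhausted)")

    for _ in range(n_clones):
        parent = int(rng.integers(0, len(profiles)))
        for _ in range(max_tries):
            n_events = int(rng.integers(events_per_edge[0], events_per_edge[1] + 1))
            child = profiles[parent].copy()
            edge_events = [draw_event(child) for _ in range(n_events)]
            if n_events == 0 or not _reducible(child, ploidy):
                break
        else:
            raise RuntimeError("could not draw an identifiable clone profile")
        profiles.append(child)
        parents.append(parent)
        events.append(edge_events)
    fractions = rng.dirichlet(np.full(n_clones, 5.0))
    return ClonalTree(bg, ploidy, np.array(profiles), parents, events, fractions)


@dataclasses.dataclass
class GroundTruth:
    """True per-cell copy numbers and everything derived from them."""

    cn: np.ndarray              # n_cells x M integer copy numbers
    clone_labels: np.ndarray    # clone index per cell, -1 for normal cells
    cell_ploidy: np.ndarray     # baseline ploidy per cell
    params: dict

    def breakpoints(self) -> np.ndarray:
        """Columns at which any cell's true copy number changes."""
        change = np.any(self.cn[:, 1:] != self.cn[:, :-1], axis=0)
        return np.nonzero(change)[0] + 1

    def acn(self) -> np.ndarray:
        return self.cn.mean(axis=1)


def simulate_counts(tree: ClonalTree, n_cells: int = 100, *,
                    depth_mean: float = 40.0, dispersion: float = np.inf,
                    normal_fraction: float = 0.10,
                    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None,
                    seed: int = 0) -> tuple[CountMatrix, GroundTruth]:
    """Draw per-cell bin counts from the clone profiles.

    counts ~ NB(mean = depth_mean * c / ploidy * g(gc), size = dispersion).
    The default dispersion is infinite, i.e. the Poisson sequencing-sampling
    limit: at 200 kb bins each count sums over thousands of short amplicons,
    so amplification variability averages out and bin-level counts from
    read-level simulation are Poisson-dominated.  Finite dispersion adds
    negative-binomial overdispersion for stress-testing against stronger
    WGA noise.  A ``normal_fraction`` of the cells is diploid regardless of
    the tree's ploidy.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    bg = tree.bingrid
    rng = np.random.default_rng(seed)
    n_normal = int(round(normal_fraction * n_cells))
    n_tumor = n_cells - n_normal
    labels = np.concatenate([
        rng.choice(tree.n_clones, size=n_tumor, p=tree.fractions),
        np.full(n_normal, -1),
    ])
    rng.shuffle(labels)
    cn = np.empty((n_cells, bg.n_bins), dtype=int)
    cell_ploidy = np.empty(n_cells, dtype=int)
    for i, lab in enumerate(labels):
        if lab < 0:
            cn[i] = 2
            cell_ploidy[i] = 2
        else:
            cn[i] = tree.clone_profiles[lab]
            cell_ploidy[i] = tree.ploidy
    g = gc_bias(bg.gc) if gc_bias is not None else np.ones(bg.n_bins)
    mean = depth_mean * cn / cell_ploidy[:, None] * g[None, :]
    if np.isinf(dispersion):
        counts = rng.poisson(mean)
    else:
        # NB as Gamma-Poisson: mean m, size r -> p = r/(r+m)
        lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
        counts = rng.poisson(lam)
    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    params = {
        "seed": seed, "ploidy": tree.ploidy, "n_cells": n_cells,
        "n_clones": tree.n_clones, "depth_mean": depth_mean,
        "dispersion": None if np.isinf(dispersion) else dispersion,
        "normal_fraction": normal_fraction,
    }
    return (CountMatrix(counts, cell_ids, bg),
            GroundTruth(cn, labels, cell_ploidy, params))


def quadratic_gc_bias(strength: float = 0.5, optimum: float = 0.45):
    """Unimodal GC bias curve g(gc) = 1 - strength * (gc - optimum)^2 * 20."""
    def g(gc: np.ndarray) -> np.ndarray:
        return np.clip(1.0 - strength * 20.0 * (gc - optimum) ** 2, 0.05, None)
    return g


def write_ground_truth(gt: GroundTruth, cell_ids: Sequence[str], prefix) -> None:
    """Persist truth as TSVs (CN matrix, breakpoints, labels) + JSON manifest."""
    import pandas as pd
    pd.DataFrame(gt.cn, index=pd.Index(list(cell_ids), name="cell_id")).to_csv(
        f"{prefix}.cn.tsv", sep="\t")
    pd.DataFrame({"breakpoint_bin": gt.breakpoints()}).to_csv(
        f"{prefix}.breakpoints.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": list(cell_ids), "clone": gt.clone_labels,
                  "ploidy": gt.cell_ploidy}).to_csv(
        f"{prefix}.labels.tsv", sep="\t", index=False)
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(gt.params, fh, indent=1)
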