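"""Benchmark protocol: simulate replicates, run the pipeline, score them.

One replicate = one simulated dataset (100 cells, 4 tumor clones + 10%
normal cells, 200 kb bins, CNAs of 3-20 Mb, ~40 reads per bin at baseline)
pushed through the full pipeline (preprocess, d=1 autoencoder for 500
epochs, per-chromosome CBS at alpha 0.1, EM copy number calling with max
copy number 10) and scored against its ground truth with the four
evaluation metrics.  The same protocol backs the test suite and the
acceptance script.

The simulated genome is 8 chromosomes of 30 Mb (1200 bins at 200 kb) —
large enough that every replicate carries its full clone structure while a
replicate completes in well under a minute on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .pipeline import evaluate_against_truth, run_pipeline
from .simulate import make_bingrid, simulate_counts, simulate_tree

#: per-replicate pipeline settings for the packaged benchmark
PROTOCOL = dict(
    n_cells=100,
    n_clones=4,
    bin_size=200_000,
    depth_mean=40.0,
    normal_fraction=0.10,
    latent_dim=1,
    epochs=500,
    learning_rate=1e-4,
    batch_size=256,
    alpha=0.1,
    n_permutations=200,
    max_cn=10,
)


@dataclasses.dataclass
class ReplicateResult:
    """Scores for one simulated dataset."""

    ploidy: int
    seed: int
    breakpoint_distance: int
    w: float
    mad: np.ndarray             # per retained cell
    delta_acn: np.ndarray       # truth - inferred, per retained cell
    ploidy_true: np.ndarray     # baseline ploidy per retained cell
    ploidy_called: np.ndarray   # round(2^(1-o)) per retained cell

    @property
    def mean_mad(self) -> float:
        return float(np.mean(self.mad))


def run_replicate(ploidy: int, seed: int, **overrides) -> ReplicateResult:
    """Simulate one dataset at the given ploidy and score the full pipeline."""
    p = {**PROTOCOL, **overrides}
    bg = make_bingrid(bin_size=p["bin_size"])
    tree = simulate_tree(p["n_clones"], ploidy=ploidy, bingrid=bg, seed=seed)
    cm, gt = simulate_counts(tree, p["n_cells"], depth_mean=p["depth_mean"],
                             normal_fraction=p["normal_fraction"], seed=seed + 1)
    res = run_pipeline(cm, latent_dim=p["latent_dim"], epochs=p["epochs"],
                       learning_rate=p["learning_rate"],
                       batch_size=p["batch_size"], alpha=p["alpha"],
                       n_permutations=p["n_permutations"], max_cn=p["max_cn"],
                       seed=seed)
    report = evaluate_against_truth(res, gt, cm)
    row_of = {c: i for i, c in enumerate(cm.cell_ids)}
    rows = np.array([row_of[c] for c in res.cell_ids()])
    return ReplicateResult(
        ploidy=ploidy,
        seed=seed,
        breakpoint_distance=report.breakpoint_distance,
        w=report.w,
        mad=report.mad,
        delta_acn=report.delta_acn,
        ploidy_true=gt.cell_ploidy[rows],
        ploidy_called=np.array([round(pr.params.ploidy) for pr in res.profiles]),
    )


def run_study(ploidy: int, n_replicates: int = 10, base_seed: int = 0,
              **overrides) -> list[ReplicateResult]:
    """Run the 10-replicate benchmark for one ancestral ploidy."""
    return [run_replicate(ploidy, _replicate_seed(base_seed, ploidy, r),
                          **overrides)
            for r in range(n_replicates)]


def _replicate_seed(base_seed: int, ploidy: int, replicate: int) -> int:
    return (base_seed * 10_007 + ploidy * 1_009 + replicate * 101) % (2 ** 31 - 1)


def summarize(results: list[ReplicateResult]) -> dict:
    """Aggregate a study the way the benchmark reports it."""
    return {
        "mean_breakpoint_distance": float(np.mean(
            [r.breakpoint_distance for r in results])),
        "mean_w": float(np.mean([r.w for r in results])),
        "mean_mad": float(np.mean(np.concatenate([r.mad for r in results]))),
        "median_delta_acn": float(np.median(
            np.concatenate([r.delta_acn for r in results]))),
        "ploidy_accuracy": float(np.mean(np.concatenate(
            [r.ploidy_called == r.ploidy_true for r in results]))),
        "n_replicates": len(results),
    }
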