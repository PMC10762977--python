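"""End-to-end driver: counts -> preprocess -> latent -> CBS -> CNA calls.

Ties the module chain together for programmatic use and the CLI.  The
ground-truth-aware entry point also maps truth onto the filtered bin set
so metrics compare like with like.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import cnacall, evaluate, latent, segment
from .io_counts import CountMatrix
from .preprocess import LRCMatrix, QCReport
from .preprocess import preprocess as preprocess_counts
from .segment import Segmentation


@dataclasses.dataclass
class PipelineResult:
    """Everything the pipeline produces for one dataset."""

    lrc: LRCMatrix
    qc: QCReport
    loss_trace: np.ndarray
    latent_z: np.ndarray
    segmentation: Segmentation
    profiles: list
    consensus_bps: np.ndarray

    def cn_matrix(self) -> np.ndarray:
        return np.stack([p.bin_cn for p in self.profiles])

    def cell_ids(self) -> list[str]:
        return [p.cell_id for p in self.profiles]


def run_pipeline(cm: CountMatrix, *, latent_dim: int = 1, epochs: int = 500,
                 learning_rate: float = 1e-4, batch_size: int = 256,
                 alpha: float = 0.1, n_permutations: int = 1000,
                 max_cn: int = 10, seed: int = 0,
                 plateau_window: int = 0,
                 preprocess_kwargs: dict | None = None) -> PipelineResult:
    """Run the full calling pipeline on a raw count matrix."""
    lrc, qc = preprocess_counts(cm, **(preprocess_kwargs or {}))
    cfg = latent.EncoderConfig(latent_dim=latent_dim, epochs=epochs,
                               learning_rate=learning_rate,
                               batch_size=batch_size, seed=seed,
                               plateau_window=plateau_window)
    model, losses = latent.train_autoencoder(lrc, cfg)
    z = latent.encode_bins(lrc, model)
    boundaries = lrc.bingrid.chrom_boundaries()
    bps = segment.segment_latent(z.z, boundaries, lrc.n_bins, alpha=alpha,
                                 n_permutations=n_permutations, seed=seed)
    seg = segment.segmentation_from_breakpoints(bps, lrc.n_bins, boundaries)
    profiles = cnacall.call_cells(lrc, seg, max_cn=max_cn)
    consensus = cnacall.consensus_breakpoints(profiles)
    return PipelineResult(lrc, qc, losses, z.z, seg, profiles, consensus)


def truth_on_filtered_bins(true_cn: np.ndarray, full_labels: list[str],
                           result: PipelineResult,
                           truth_cell_ids: list[str]) -> np.ndarray:
    """Subset a truth CN matrix to the bins and cells the pipeline retained."""
    kept_labels = result.lrc.bingrid.labels()
    col_of = {lab: k for k, lab in enumerate(full_labels)}
    cols = np.array([col_of[lab] for lab in kept_labels])
    row_of = {cid: i for i, cid in enumerate(truth_cell_ids)}
    rows = np.array([row_of[cid] for cid in result.cell_ids()])
    return true_cn[np.ix_(rows, cols)]


def evaluate_against_truth(result: PipelineResult, gt, cm: CountMatrix):
    """EvalReport of a pipeline run versus its simulation ground truth.

    True breakpoints are recomputed from the truth CN matrix restricted to
    the retained bins, so the comparison shares one coordinate space with
    the inferred consensus breakpoints.
    """
    true_cn = truth_on_filtered_bins(gt.cn, cm.bingrid.labels(), result, cm.cell_ids)
    change = np.any(true_cn[:, 1:] != true_cn[:, :-1], axis=0)
    real_bps = np.nonzero(change)[0] + 1
    return evaluate.evaluate_profiles(true_cn, result.cn_matrix(),
                                      real_bps, result.consensus_bps)
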