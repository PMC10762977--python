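"""Bin-wise representation learning with a fully-connected autoencoder.

The sample unit is the genomic bin: each bin's cross-cell LRC vector
(length N) is encoded through fully-connected layers of 256, 128 and 64
units into a d-dimensional code (default d=1), and decoded through the
mirrored structure.  Training minimizes the per-sample reconstruction loss

    L(y, y_hat) = ||y - y_hat||^2 / (2 N)

by Adam on shuffled mini-batches.  The network is small enough that a
plain numpy implementation (explicit forward/backward passes) trains in
seconds on CPU at typical scDNA-seq bin counts; layer widths, optimizer
state and the shuffling stream are all driven by a single seed so runs
are exactly reproducible.

Hidden layers use a leaky ReLU; the latent code and the reconstruction
are linear so both stay unbounded like LRC itself.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import LRCMatrix

_HIDDEN = (256, 128, 64)
_LEAK = 0.01


@dataclasses.dataclass
class EncoderConfig:
    """Training hyperparameters for the bin autoencoder."""

    latent_dim: int = 1
    epochs: int = 500
    learning_rate: float = 1e-4
    batch_size: int = 256
    seed: int = 0
    #: stop early once the epoch-mean loss improves by less than
    #: ``plateau_rtol`` (relative) over ``plateau_window`` epochs; 0 disables
    plateau_window: int = 0
    plateau_rtol: float = 1e-3

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclasses.dataclass
class ModelState:
    """Trained weights: list of (W, b) per layer, encoder then decoder."""

    weights: list
    n_features: int
    latent_dim: int

    @property
    def n_encoder_layers(self) -> int:
        return len(_HIDDEN) + 1


@dataclasses.dataclass(frozen=True)
class LatentMatrix:
    """d x M latent codes, columns aligned with the LRC bin order."""

    z: np.ndarray
    bingrid: object

    @property
    def d(self) -> int:
        return self.z.shape[0]

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]


def _init_weights(sizes, rng) -> list:
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(1.0 / fan_in)  # fan-in uniform init
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        weights.append((W, b))
    return weights


def _forward(weights, y, n_linear_heads):
    """Return layer inputs (pre-activation cache) and the final output.

    ``n_linear_heads`` holds the indices of layers with a linear output
    (the latent head and the reconstruction head); all others are leaky ReLU.
    """
    activations = [y]
    pre = []
    h = y
    for li, (W, b) in enumerate(weights):
        a = h @ W + b
        pre.append(a)
        h = a if li in n_linear_heads else np.where(a > 0, a, _LEAK * a)
        activations.append(h)
    return activations, pre


def train_autoencoder(X: LRCMatrix, cfg: EncoderConfig) -> tuple[ModelState, np.ndarray]:
    """Train on the M bin columns of X; returns the model and per-epoch mean loss."""
    data = X.lrc.T.astype(np.float32)  # M samples x N features
    M, N = data.shape
    if X.n_cells < 2:
        raise ValueError("need at least 2 cells to learn bin representations")
    sizes = [N, *_HIDDEN, cfg.latent_dim, *reversed(_HIDDEN), N]
    rng = np.random.default_rng(cfg.seed)
    weights = [(W.astype(np.float32), b.astype(np.float32))
               for W, b in _init_weights(sizes, rng)]
    linear_heads = {len(_HIDDEN), len(sizes) - 2}  # latent code + reconstruction

    lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    m_t = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v_t = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    step = 0
    losses = np.empty(cfg.epochs)
    n_epochs_run = cfg.epochs
    for epoch in range(cfg.epochs):
        order = rng.permutation(M)
        epoch_loss = 0.0
        for start in range(0, M, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            B = batch.shape[0]
            acts, pre = _forward(weights, batch, linear_heads)
            resid = acts[-1] - batch
            loss = float(np.sum(resid ** 2) / (2.0 * N * B))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "non-finite reconstruction loss; check that the input is "
                    "normalized LRC data")
            epoch_loss += loss * B
            # backward
            grad = resid / (N * B)  # dL/d(output), linear head
            grads = [None] * len(weights)
            for li in range(len(weights) - 1, -1, -1):
                W, b = weights[li]
                gW = acts[li].T @ grad
                gb = grad.sum(axis=0)
                grads[li] = (gW, gb)
                if li > 0:
                    grad = grad @ W.T
                    if (li - 1) not in linear_heads:
                        a = pre[li - 1]
                        grad = grad * np.where(a > 0, 1.0, _LEAK)
            # Adam update
            step += 1
            new_weights = []
            for li, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
                mW, mb = m_t[li]
                vW, vb = v_t[li]
                mW = b1 * mW + (1 - b1) * gW
                mb = b1 * mb + (1 - b1) * gb
                vW = b2 * vW + (1 - b2) * gW ** 2
                vb = b2 * vb + (1 - b2) * gb ** 2
                m_t[li] = (mW, mb)
                v_t[li] = (vW, vb)
                c1 = 1 - b1 ** step
                c2 = 1 - b2 ** step
                W = W - lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
                b = b - lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
                new_weights.append((W, b))
            weights = new_weights
        losses[epoch] = epoch_loss / M
        if cfg.plateau_window and epoch >= cfg.plateau_window:
            prev = losses[epoch - cfg.plateau_window]
            if prev - losses[epoch] < cfg.plateau_rtol * abs(prev):
                n_epochs_run = epoch + 1
                break
    return ModelState(weights, N, cfg.latent_dim), losses[:n_epochs_run]


def encode_bins(X: LRCMatrix, model: ModelState) -> LatentMatrix:
    """Project each bin column through the encoder; returns Z (d x M)."""
    data = X.lrc.T.astype(float)
    if data.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} cells, got {data.shape[1]}")
    enc = model.weights[: model.n_encoder_layers]
    linear_heads = {len(_HIDDEN)}
    acts, _ = _forward(enc, data, linear_heads)
    return LatentMatrix(acts[-1].T, X.bingrid)


def reconstruct_bins(X: LRCMatrix, model: ModelState) -> np.ndarray:
    """Full encode-decode pass; used for loss inspection."""
    data = X.lrc.T.astype(float)
    linear_heads = {len(_HIDDEN), 2 * len(_HIDDEN) + 1}
    acts, _ = _forward(model.weights, data, linear_heads)
    return acts[-1].T


def reconstruction_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Per-sample loss ||y - y_hat||^2 / (2 N), averaged over samples if 2-D."""
    y = np.atleast_2d(y)
    y_hat = np.atleast_2d(y_hat)
    n = y.shape[1]
    return float(np.mean(np.sum((y - y_hat) ** 2, axis=1) / (2.0 * n)))


def save_model(model: ModelState, path) -> None:
    """Persist weights as a plain-text npz-free TSV-like dump."""
    import json
    payload = {
        "n_features": model.n_features,
        "latent_dim": model.latent_dim,
        "layers": [[W.tolist(), b.tolist()] for W, b in model.weights],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ModelState:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    weights = [(np.asarray(W), np.asarray(b)) for W, b in payload["layers"]]
    return ModelState(weights, payload["n_features"], payload["latent_dim"])
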