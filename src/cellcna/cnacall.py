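"""Per-cell copy number calling by an EM-fitted Gaussian mixture over segments.

For one cell, the LRC values of segment k are modeled as i.i.d. normal
with state-dependent mean

    mu_s = log2(0.5 c_s) + o

where c_s is the copy number of state s and o is a cell-level baseline
shift absorbing aneuploidy (o = -log2(0.5 ploidy) when the genome sits at
its baseline state).  A shared sigma and mixing weights pi_s complete the
parameter set theta = (o, sigma, pi), fitted by EM from a linear grid of
initial o values; the start with the highest final log-likelihood wins,
with near-ties broken toward the ploidy closest to 2.

All E/M computations use per-segment sufficient statistics (L_k, sum x,
sum x^2), so EM cost is independent of bin count, and every start in the
o grid is updated simultaneously as one vectorized batch.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .preprocess import LRC_FLOOR
from .segment import Segmentation

#: The copy-number-0 component models floored zero-count bins.  Preprocessing
#: clamps corrected counts at LRC_FLOOR before log2, so every such bin sits at
#: exactly log2(LRC_FLOOR) = -3 regardless of the cell's baseline shift; the
#: state-0 mean is therefore that constant and does not move with o (and state
#: 0 contributes nothing to the o update).  Reported copy number remains 0.
ZERO_STATE_MEAN = float(np.log2(LRC_FLOOR))

SIGMA_FLOOR = 1e-4
LOG2PI = float(np.log(2.0 * np.pi))


@dataclasses.dataclass
class MixtureParams:
    """Fitted mixture parameters for one cell."""

    o: float
    sigma: float
    pi: np.ndarray
    states: np.ndarray          # integer copy numbers 0..max_cn
    log_likelihood: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if abs(float(self.pi.sum()) - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.diff(self.states) <= 0):
            raise ValueError("states must be strictly increasing")

    @property
    def ploidy(self) -> float:
        """Baseline ploidy implied by o via o = -log2(0.5 ploidy)."""
        return float(2.0 ** (1.0 - self.o))


@dataclasses.dataclass
class CellCNProfile:
    """Copy number calls for one cell on a shared segmentation."""

    cell_id: str
    seg_cn: np.ndarray          # per-segment integer copy number
    gamma: np.ndarray           # K x S posterior
    bin_cn: np.ndarray          # per-bin expansion
    params: MixtureParams

    @property
    def acn(self) -> float:
        """Average copy number over bins."""
        return float(np.mean(self.bin_cn))


def state_bases(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-state (base mean, o indicator): mu_s = base_s + o * ind_s.

    States with c >= 1 have base log2(0.5 c) and move with o; state 0 is
    pinned at the LRC floor and does not.
    """
    vals = states.astype(float)
    with np.errstate(divide="ignore"):
        base = np.log2(0.5 * vals)
    ind = np.ones_like(base)
    base[vals == 0] = ZERO_STATE_MEAN
    ind[vals == 0] = 0.0
    return base, ind


def state_mean(c_s: float, o: float) -> float:
    """mu_s = log2(0.5 c_s) + o for c >= 1; the LRC floor for c = 0."""
    if c_s == 0:
        return ZERO_STATE_MEAN
    return float(np.log2(0.5 * c_s) + o)


def segment_loglik(x_k: np.ndarray, mu: float, sigma: float) -> float:
    """Sum of log normal densities of one segment's LRC values."""
    x_k = np.asarray(x_k, dtype=float)
    L = x_k.size
    return float(-0.5 * L * (LOG2PI + 2.0 * np.log(sigma))
                 - np.sum((x_k - mu) ** 2) / (2.0 * sigma ** 2))


def _suffstats(x: Sequence[np.ndarray]):
    L = np.array([len(xk) for xk in x], dtype=float)
    sx = np.array([np.sum(xk) for xk in x], dtype=float)
    sxx = np.array([np.sum(np.square(xk)) for xk in x], dtype=float)
    return L, sx, sxx


def _log_components(L, sx, sxx, base, ind, o, sigma):
    """K x S matrix of log f(x_k | state s) from sufficient statistics.

    Supports a leading grid axis on o/sigma: o of shape (...,), output
    (..., K, S).
    """
    o = np.asarray(o, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    mu = base + o[..., None, None] * ind                 # (..., 1, S)
    Lk = L[:, None]
    return (-0.5 * Lk * (LOG2PI + 2.0 * np.log(sigma)[..., None, None])
            - (sxx[:, None] - 2.0 * mu * sx[:, None] + Lk * mu ** 2)
            / (2.0 * sigma[..., None, None] ** 2))


def e_step(x: Sequence[np.ndarray], params: MixtureParams) -> np.ndarray:
    """Posterior gamma_ks = pi_s f(x_k|s) / f(x_k|theta), in log space."""
    L, sx, sxx = _suffstats(x)
    base, ind = state_bases(params.states)
    ll = _log_components(L, sx, sxx, base, ind, params.o, params.sigma)
    with np.errstate(divide="ignore"):
        logw = ll + np.log(params.pi)
    return np.exp(logw - logsumexp(logw, axis=-1, keepdims=True))


def m_step(x: Sequence[np.ndarray], gamma: np.ndarray,
           states: np.ndarray) -> MixtureParams:
    """Closed-form updates of (o, sigma, pi) maximizing the EM objective."""
    L, sx, sxx = _suffstats(x)
    base, ind = state_bases(states)
    o, sigma = _m_step_core(L, sx, sxx, base, ind, gamma)
    pi = gamma.sum(axis=0) / gamma.shape[0]
    ll = _loglik(L, sx, sxx, base, ind, o, sigma, pi)
    return MixtureParams(float(o), float(sigma), pi, states, float(ll))


def _m_step_core(L, sx, sxx, base, ind, gamma):
    """o and sigma updates; gamma may carry a leading grid axis.

    Only states that move with o (ind == 1) enter the o update; the
    pinned state 0 still contributes residuals to sigma.
    """
    Lk = L[:, None]
    denom_o = np.sum(gamma * Lk * ind, axis=(-2, -1))
    num_o = np.sum(gamma * (sx[:, None] - Lk * base) * ind, axis=(-2, -1))
    o = num_o / np.maximum(denom_o, 1e-12)
    mu = base + np.asarray(o)[..., None, None] * ind
    denom = np.sum(gamma * Lk, axis=(-2, -1))
    ss = np.sum(gamma * (sxx[:, None] - 2.0 * mu * sx[:, None]
                         + Lk * mu ** 2), axis=(-2, -1))
    sigma = np.sqrt(np.maximum(ss / denom, SIGMA_FLOOR ** 2))
    return o, sigma


def _loglik(L, sx, sxx, base, ind, o, sigma, pi):
    """Observed-data log-likelihood sum_k log sum_s pi_s f(x_k|s)."""
    ll = _log_components(L, sx, sxx, base, ind, o, sigma)
    with np.errstate(divide="ignore"):
        logw = ll + np.log(pi)[..., None, :]
    return np.sum(logsumexp(logw, axis=-1), axis=-1)


def default_o_grid() -> np.ndarray:
    """61 starts in [-2, 1] step 0.05, bracketing ploidy ~1 to ~8."""
    return np.round(np.arange(-2.0, 1.0 + 1e-9, 0.05), 10)


#: near-tie window (absolute log-likelihood units) within which the start
#: with ploidy nearest 2 is preferred.  It covers the numerical wobble
#: between independently-converged EM fixed points of *exactly* degenerate
#: solutions (a uniformly rescaled copy number profile fits the normalized
#: data identically) plus the residual misfit a rescaled baseline can absorb
#: through interpolating states; genuine evidence gaps are larger.
TIE_WINDOW_LL = 2.0


def _em_engine(L, sx, sxx, base, ind, o_grid, sigma0, tol, max_iter):
    """Run EM from every o start for a batch of cells, fully vectorized.

    Shapes: L (N, K), sx/sxx (N, K), sigma0 (N,), o_grid (G,).  A segment
    with L == 0 for a cell contributes nothing to that cell's fit (used to
    exclude model-violating segments from parameter estimation).  Every
    (cell, start) chain is an independent EM run; converged chains are
    frozen out of the batch.
    Returns o, sigma, ll of shape (N, G) and pi of shape (N, G, S).
    """
    N, K = sx.shape
    G, S = len(o_grid), len(base)
    P = N * G
    cell_of = np.repeat(np.arange(N), G)
    o = np.tile(o_grid, N)
    sigma = np.repeat(sigma0, G)
    pi = np.full((P, S), 1.0 / S)
    ll = np.full(P, -np.inf)
    active = np.arange(P)
    for _ in range(max_iter):
        cells = cell_of[active]
        oa, sa, pa = o[active], sigma[active], pi[active]
        Lk = L[cells, :, None]                      # (p, K, 1)
        sxg = sx[cells, :, None]
        sxxg = sxx[cells, :, None]
        mu = base + oa[:, None, None] * ind         # (p, 1, S)
        comp = (-0.5 * Lk * (LOG2PI + 2.0 * np.log(sa)[:, None, None])
                - (sxxg - 2.0 * mu * sxg + Lk * mu ** 2)
                / (2.0 * sa[:, None, None] ** 2))   # (p, K, S)
        with np.errstate(divide="ignore"):
            logw = comp + np.log(np.maximum(pa, 1e-300))[:, None, :]
        gamma = np.exp(logw - logsumexp(logw, axis=-1, keepdims=True))
        denom = np.sum(gamma * Lk, axis=(-2, -1))
        oa = (np.sum(gamma * (sxg - Lk * base) * ind, axis=(-2, -1))
              / np.maximum(np.sum(gamma * Lk * ind, axis=(-2, -1)), 1e-12))
        mu = base + oa[:, None, None] * ind
        ss = np.sum(gamma * (sxxg - 2.0 * mu * sxg + Lk * mu ** 2), axis=(-2, -1))
        sa = np.sqrt(np.maximum(ss / denom, SIGMA_FLOOR ** 2))
        pa = gamma.sum(axis=-2) / K
        comp = (-0.5 * Lk * (LOG2PI + 2.0 * np.log(sa)[:, None, None])
                - (sxxg - 2.0 * mu * sxg + Lk * mu ** 2)
                / (2.0 * sa[:, None, None] ** 2))
        with np.errstate(divide="ignore"):
            logw = comp + np.log(np.maximum(pa, 1e-300))[:, None, :]
        lla = np.sum(logsumexp(logw, axis=-1), axis=-1)
        done = np.abs(lla - ll[active]) < tol * np.maximum(np.abs(lla), 1.0)
        o[active], sigma[active], pi[active], ll[active] = oa, sa, pa, lla
        active = active[~done]
        if active.size == 0:
            break
    shape = (N, G)
    return (o.reshape(shape), sigma.reshape(shape),
            pi.reshape(N, G, S), ll.reshape(shape))


#: segments whose within-segment LRC variance exceeds this multiple of the
#: cell's median segment variance (minimum length 5) violate the
#: homogeneous-segment assumption so grossly that no single state can model
#: them -- a floored zero-count stretch inside a deletion, or a mixture of
#: levels a full copy-ratio apart (extra variance >= 0.16/sigma^2 ~ 2.8x).
#: They are excluded from parameter estimation for that cell (their states
#: are still assigned from the fitted model afterwards).  Milder mixtures
#: (adjacent copy numbers) are kept: they are also the segments carrying
#: clone-private CNAs, i.e. the cell's ploidy evidence.
MIXED_SEGMENT_VAR_RATIO = 3.5
MIXED_SEGMENT_MIN_LEN = 5


#: breakpoint localization is only bin-accurate, so the outermost bin at
#: each end of a segment may belong to the neighboring copy number state;
#: segments of at least this length are eroded by one bin per edge when
#: accumulating the sufficient statistics used for parameter estimation
#: (full segments are still used when assigning states).
EDGE_TRIM_MIN_LEN = 4


def _trimmed_bounds(bounds):
    out = []
    for lo, hi in bounds:
        if hi - lo >= EDGE_TRIM_MIN_LEN:
            out.append((lo + 1, hi - 1))
        else:
            out.append((lo, hi))
    return out


def _mixed_segment_flags(L, sx, sxx):
    """Boolean (N, K) flags of model-violating segments per cell."""
    with np.errstate(invalid="ignore", divide="ignore"):
        v = sxx / L - (sx / L) ** 2
    eligible = L >= MIXED_SEGMENT_MIN_LEN
    flags = np.zeros_like(v, dtype=bool)
    for i in range(v.shape[0]):
        if not eligible[i].any():
            continue
        ref = np.median(v[i][eligible[i]])
        flags[i] = eligible[i] & (v[i] > MIXED_SEGMENT_VAR_RATIO * max(ref, 1e-12))
    return flags


def _select_start(o, sigma, pi, ll, states, ploidy_range, n_bins, n_segments):
    """Pick the winning start for one cell (1-D slices over the grid).

    Candidates are ranked by a BIC-style score: log-likelihood minus
    0.5 * ln(n_bins) per occupied mixture state.  A uniformly rescaled
    interpretation of the profile occupies the same number of states and
    fits identically, so it ties and the ploidy-nearest-2 rule decides; a
    spuriously dense interpretation (higher baseline whose intermediate
    states soak up residual misfit) occupies extra states and loses more
    to the penalty than it absorbs.
    """
    implied = 2.0 ** (1.0 - o)
    allowed = (implied >= ploidy_range[0]) & (implied <= ploidy_range[1])
    if not allowed.any():
        allowed = np.ones_like(allowed)
    occupied = np.sum(pi > 0.5 / max(n_segments, 1), axis=-1)
    score = ll - 0.5 * np.log(max(n_bins, 2)) * occupied
    ll_sel = np.where(allowed, score, -np.inf)
    best = float(np.max(ll_sel))
    near = np.nonzero(ll_sel >= best - TIE_WINDOW_LL)[0]
    # among near-ties prefer ploidy nearest 2, i.e. |o| smallest
    win = int(near[np.argmin(np.abs(o[near]))])
    return MixtureParams(float(o[win]), float(sigma[win]),
                         pi[win] / pi[win].sum(), states, float(ll[win]))


def fit_cell(x: Sequence[np.ndarray], *, max_cn: int = 10,
             o_grid: np.ndarray | None = None, tol: float = 1e-6,
             max_iter: int = 200, ploidy_range: tuple[float, float] = (1.0, 4.5),
             ) -> tuple[MixtureParams, np.ndarray]:
    """EM from every start in o_grid; returns best params and its gamma.

    sigma is initialized to the standard deviation of the cell's pooled LRC,
    pi to uniform.  Selection: highest final log-likelihood among solutions
    whose implied baseline ploidy 2^(1-o) lies in ``ploidy_range`` (very high
    baselines act as arbitrarily dense state grids that absorb any model
    misfit, so they are excluded as biologically implausible); near-ties
    (within TIE_WINDOW_LL) are broken toward ploidy nearest 2.
    """
    if o_grid is None:
        o_grid = default_o_grid()
    o_grid = np.asarray(o_grid, dtype=float)
    states = np.arange(max_cn + 1)
    base, ind = state_bases(states)
    x_fit = [xk[1:-1] if len(xk) >= EDGE_TRIM_MIN_LEN else xk for xk in x]
    L, sx, sxx = _suffstats(x_fit)
    flags = _mixed_segment_flags(L[None], sx[None], sxx[None])
    L_fit = np.where(flags, 0.0, L[None])
    sx_fit = np.where(flags, 0.0, sx[None])
    sxx_fit = np.where(flags, 0.0, sxx[None])
    pooled = np.concatenate([np.asarray(xk, float) for xk in x])
    sigma0 = np.array([max(float(np.std(pooled)), SIGMA_FLOOR)])
    o, sigma, pi, ll = _em_engine(L_fit, sx_fit, sxx_fit, base, ind, o_grid,
                                  sigma0, tol, max_iter)
    if not np.all(np.isfinite(ll)):
        bad = np.nonzero(~np.isfinite(ll[0]))[0]
        raise FloatingPointError(
            f"EM diverged for starts o0={o_grid[bad][:5]} (non-finite likelihood)")
    params = _select_start(o[0], sigma[0], pi[0], ll[0], states, ploidy_range,
                           int(L_fit.sum()), int((L_fit[0] > 0).sum()))
    gamma_win = e_step(x, params)
    return params, gamma_win


def assign_states(gamma: np.ndarray) -> np.ndarray:
    """Most probable state per segment; ties resolve to the lower copy number."""
    return np.argmax(gamma, axis=-1)


def postprocess_amplified(seg_cn: np.ndarray, x: Sequence[np.ndarray],
                          params: MixtureParams, max_cn: int) -> np.ndarray:
    """Re-estimate copy number of segments stuck at the top mixture state.

    The state set caps copy numbers at max_cn, so highly amplified segments
    are underestimated; for segments assigned the maximal state the copy
    number is recomputed by inverting the state-mean relation,
    c = round(2^(mean LRC - o + 1)), and kept only if it exceeds max_cn.
    """
    out = seg_cn.copy()
    for k, cn in enumerate(seg_cn):
        if cn == max_cn:
            xbar = float(np.mean(x[k]))
            c_new = int(np.round(2.0 ** (xbar - params.o + 1.0)))
            if c_new > max_cn:
                out[k] = c_new
    return out


def expand_to_bins(seg_cn: np.ndarray, seg: Segmentation) -> np.ndarray:
    return np.repeat(seg_cn, seg.lengths)


def call_cell(cell_id: str, lrc_row: np.ndarray, seg: Segmentation, *,
              max_cn: int = 10, o_grid: np.ndarray | None = None,
              tol: float = 1e-6, max_iter: int = 200,
              postprocess: bool = True) -> CellCNProfile:
    """Full calling pipeline for one cell on a shared segmentation."""
    x = [lrc_row[lo:hi] for lo, hi in seg.bounds()]
    params, gamma = fit_cell(x, max_cn=max_cn, o_grid=o_grid, tol=tol,
                             max_iter=max_iter)
    seg_cn = params.states[assign_states(gamma)]
    if postprocess:
        seg_cn = postprocess_amplified(seg_cn, x, params, max_cn)
    bin_cn = expand_to_bins(seg_cn, seg)
    return CellCNProfile(cell_id, seg_cn, gamma, bin_cn, params)


def call_cells(lrc, seg: Segmentation, *, max_cn: int = 10,
               o_grid: np.ndarray | None = None, tol: float = 1e-6,
               max_iter: int = 200, ploidy_range: tuple[float, float] = (1.0, 4.5),
               postprocess: bool = True) -> list[CellCNProfile]:
    """Call every cell of an LRCMatrix independently.

    Equivalent to ``call_cell`` per cell but runs the EM for all cells and
    all o starts as one vectorized batch.
    """
    if o_grid is None:
        o_grid = default_o_grid()
    o_grid = np.asarray(o_grid, dtype=float)
    states = np.arange(max_cn + 1)
    base, ind = state_bases(states)
    bounds = seg.bounds()
    K = len(bounds)
    trimmed = _trimmed_bounds(bounds)
    L = np.array([hi - lo for lo, hi in trimmed], dtype=float)
    seg_ids = np.full(seg.n_bins, -1)
    for k, (lo, hi) in enumerate(trimmed):
        seg_ids[lo:hi] = k
    inside = seg_ids >= 0
    X = lrc.lrc
    sx = np.stack([np.bincount(seg_ids[inside], weights=row[inside],
                               minlength=K) for row in X])
    sxx = np.stack([np.bincount(seg_ids[inside], weights=row[inside] ** 2,
                                minlength=K) for row in X])
    Lb = np.broadcast_to(L, sx.shape)
    flags = _mixed_segment_flags(Lb, sx, sxx)
    sigma0 = np.maximum(X.std(axis=1), SIGMA_FLOOR)
    o, sigma, pi, ll = _em_engine(np.where(flags, 0.0, Lb),
                                  np.where(flags, 0.0, sx),
                                  np.where(flags, 0.0, sxx),
                                  base, ind, o_grid, sigma0, tol, max_iter)
    profiles = []
    for i, cid in enumerate(lrc.cell_ids):
        Li = np.where(flags[i], 0.0, L)
        params = _select_start(o[i], sigma[i], pi[i], ll[i], states,
                               ploidy_range, int(Li.sum()), int((Li > 0).sum()))
        x = [X[i, lo:hi] for lo, hi in bounds]
        gamma = e_step(x, params)
        seg_cn = states[assign_states(gamma)]
        if postprocess:
            seg_cn = postprocess_amplified(seg_cn, x, params, max_cn)
        profiles.append(CellCNProfile(cid, seg_cn, gamma,
                                      expand_to_bins(seg_cn, seg), params))
    return profiles


def merge_equal_cn(profile: CellCNProfile, seg: Segmentation,
                   chrom_of_segment: np.ndarray | None = None) -> list[tuple]:
    """Merge adjacent same-chromosome segments with equal copy number.

    Returns (start_bin, end_bin, copy_number) tuples; per-bin copy numbers
    are unchanged by construction.
    """
    bounds = seg.bounds()
    merged: list[list] = []
    for k, ((lo, hi), cn) in enumerate(zip(bounds, profile.seg_cn)):
        same_chrom = (merged and (chrom_of_segment is None
                                  or chrom_of_segment[k] == chrom_of_segment[k - 1]))
        if same_chrom and merged[-1][2] == cn and merged[-1][1] == lo:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi, int(cn)])
    return [tuple(row) for row in merged]


def consensus_breakpoints(profiles: Sequence[CellCNProfile]) -> np.ndarray:
    """Bin indices where at least one cell changes copy number."""
    if not profiles:
        raise ValueError("need at least one cell profile")
    cn = np.stack([p.bin_cn for p in profiles])
    change = np.any(cn[:, 1:] != cn[:, :-1], axis=0)
    return np.nonzero(change)[0] + 1
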