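# Methods

`cellcna` infers absolute single-cell copy number profiles from shallow
scDNA-seq bin read counts. The central idea is to treat breakpoint
detection as *cross-cell* segmentation: each genomic bin is summarized by
its vector of log2 read counts across all cells, compressed to a
low-dimensional code by an autoencoder, and segmented along the genome
with circular binary segmentation (CBS). Copy numbers are then called per
cell on the shared segments with an EM-fitted Gaussian mixture whose
baseline-shift parameter encodes cell ploidy.

## Preprocessing

Input is an integer count matrix (N cells x M fixed-width bins, default
200 kb) plus per-bin GC fraction and mappability tracks. The steps run in
a fixed order:

1. **Track filter.** Bins with GC < 10%, GC > 90%, or mappability < 0.9
   are removed. (The mappability comparator is configurable; removing
   *low*-mappability bins is the standard direction — high mappability is
   desirable.)
2. **Library-size normalization.** Each cell's counts are divided by
   that cell's mean count, making rows comparable across cells.
3. **Extreme-bin filter.** Bins whose across-cell mean normalized count
   falls strictly below the 1% quantile or strictly above the 99%
   quantile of bin means are removed; boundary ties are kept, so
   degenerate all-equal inputs lose nothing.
4. **Cell filter.** The Gini coefficient
   G = Σ_ij |x_i − x_j| / (2 n² x̄) of each cell's raw bin counts
   measures coverage unevenness; cells with G ≥ 0.3 are dropped.
5. **Median normalization.** Per cell, r̂_k = r_k · m / m_k, where m is
   the cell's median over all bins and m_k the median over bins in bin
   k's stratum. Strata are equal-width value bins (GC width 0.01,
   mappability width 0.02); GC correction is applied first, then
   mappability correction.
6. **Log transform.** LRC = log2(max(r̂, ε)) with ε = 0.125, plus the
   plug-in Jensen correction 1/(2·x·ln2) per bin (x the raw count,
   zero-count bins exempt). E[log₂X] for a counting variable sits below
   log₂E[X] by 1/(2·E[X]·ln2) — about 0.02 at 40 reads but 0.06 at 13 —
   so without the correction low-copy segments land systematically below
   their log2 copy ratio, a displacement that accumulates over segment
   length and biases the downstream baseline fit.

The floor ε = 0.125 is deliberate: the mixture model represents copy
number 0 by a pseudo copy number of 0.25, whose expected LRC is
log2(0.5 · 0.25) + o = −3 + o. A zero-count bin floored at 0.125 lands at
LRC −3, i.e. exactly on that state's mean, so homozygous deletions are
absorbed by the copy-0 state instead of acting as −13 outliers that
inflate the fitted noise scale. A much smaller floor destabilizes σ for
every cell that carries a homozygous deletion.

For a cell with average copy number ā, library-size normalization places
a copy-c region at LRC ≈ log2(c) − log2(ā); the mixture's baseline shift
absorbs the −log2(ā) term.

## Bin representation learning

Each bin's cross-cell LRC vector (length N) is a training sample for a
fully-connected autoencoder: encoder 256-128-64-d, mirrored decoder,
leaky-ReLU hidden activations, linear latent and output heads (LRC is
unbounded, so the code and reconstruction stay unbounded too). Training
minimizes the reconstruction loss ‖y − ŷ‖²/(2N) with Adam at learning
rate 1e-4, batch size 256, 500 epochs, shuffled bins per epoch. All
randomness (init, shuffling) derives from one seed; runs are exactly
reproducible. The default latent dimension is d = 1; d = 2 trades some
extra breakpoints for sensitivity to low-prevalence CNAs.

The network is implemented directly in numpy (explicit forward/backward
passes, float32): at 10⁵ parameters and a few thousand samples, a tensor
framework adds nothing but overhead on CPU.

Because bins are encoded independently, i.i.d. bins map to i.i.d. codes,
which is exactly the exchangeability the downstream permutation test
needs.

## Segmentation

Each latent row is segmented per chromosome by canonical CBS: find the
circular arc maximizing the between-arc |t|-like statistic (residual
scale omitted — it is permutation-invariant), accept the split if its
seeded permutation p-value (1 + #exceedances)/(1 + P) is below α = 0.1,
and recurse until nothing is accepted. After the recursion, each
breakpoint is re-validated as a single split of the region between its
neighboring breakpoints and backward-eliminated until all survivors are
significant at the same α. This validation pass is what keeps the
liberal α = 0.1 usable: without it, 2–4-bin blips of amplified latent
noise in flat regions are accepted against the whole-chromosome
background, single cells then flip copy number across the resulting
slivers, and the final breakpoint count inflates by 20–40%.

Breakpoint sets from all latent rows are merged by union. Chromosome
starts are always segment boundaries; a breakpoint at b separates bins
[.., b−1] and [b, ..] (0-based, half-open everywhere).

## Copy number calling

Per cell, the LRC values of segment k are modeled as i.i.d. normal with
mean μ_s = log2(0.5 c_s) + o for copy-number states c_s ∈ {1, …, 10} and
shared σ; states mix with weights π_s. The copy-0 state is pinned at the
LRC floor: preprocessing clamps corrected counts at ε = 0.125, so every
zero-count bin sits at exactly log2(ε) = −3 *independently of o*, and the
state-0 mean is that constant (state 0 also contributes nothing to the o
update). Without the pinning, a cell with a homozygous deletion pays
|o|²·L/(2σ²) per deleted bin under its own correct interpretation, which
single-handedly flips ploidy calls.

EM alternates the segment-level posterior γ_ks ∝ π_s f(x_k|s) (log-space,
per-segment sufficient statistics, so cost is independent of bin count)
with closed-form updates: o is the γ-weighted mean of
x_ki − log2(0.5 c_s) over states 1…10; σ the γ-weighted RMS about μ_s
(floored at 1e-4); π_s = Σ_k γ_ks / K. It runs from 61 starts
o₀ ∈ [−2, 1] (step 0.05), σ initialized to the cell's pooled LRC standard
deviation, π uniform, until the relative log-likelihood change is below
1e-6 or 200 iterations. All starts — and all cells — are updated as one
vectorized batch, with converged cells frozen out.

**Which data enter the fit.** Two robustness filters apply to parameter
estimation only (state assignment afterwards always uses the full data):
segments are eroded by one bin per edge (breakpoint localization is only
bin-accurate, and a contaminating edge bin shifts a segment mean by a
systematic amount that rescaled-baseline interpretations exploit), and
segments whose within-segment variance exceeds 3.5× the cell's median
segment variance are dropped for that cell (no single state can model
them — typically a floored zero-count stretch inside a deletion, or a
mixture of levels a full copy-ratio apart). Milder mixtures are kept
deliberately: adjacent-copy mixtures are also the segments carrying
clone-private CNAs, i.e. the cell's ploidy evidence.

**Model selection across starts.** Candidates are ranked by a BIC-style
score — the final log-likelihood minus 0.5·ln(n_bins) per occupied state
(π_s above half a segment's worth) — subject to the implied baseline
ploidy 2^(1−o) lying in [1, 4.5] (configurable; the default covers the
near-universal range up to one whole-genome doubling, and higher
baselines act as ever-denser state grids that absorb residual misfit of
the shared-σ Gaussian). The occupancy term makes an exactly rescaled
interpretation — which fits identically but is wrong — tie rather than
win, and near-ties within 2 log-likelihood units resolve to the ploidy
nearest 2, which is also how a featureless diploid profile must be
resolved. A cell whose profile is an exact integer rescaling of a flatter
one is unidentifiable in principle; the simulator refuses to generate
such tumor clones, and for real data the resolution is the documented
lowest-consistent-ploidy convention.

Segment states are the posterior argmax (ties to the lower copy number).
Segments assigned the top state are re-estimated by inverting the state
mean, c = round(2^(x̄_k − o + 1)), and replaced when the result exceeds
the state cap — without this, amplifications above copy 10 are clipped.
Adjacent same-chromosome segments with equal copy number are merged per
cell; the consensus breakpoint set keeps a boundary iff at least one cell
changes copy number across it. A cell's ploidy estimate is 2^(1−o) (≈ its
average copy number when the baseline state dominates).

## Synthetic data

The simulator generates ground-truthed bin counts from a random clonal
tree. The root is a uniform ancestral state at ploidy 2, 3 or 4; each
sampled tumor clone hangs off a random existing node and carries 1–3 CNA
events (lengths uniform in 3–20 Mb, copy change in {−2, −1, +1, +2},
clipped at 0). The root itself is not a sampled clone, and any clone
whose profile is an exact integer rescaling of a lower baseline (all
c·b/ploidy integral for some b < ploidy) is redrawn: such a cell's ploidy
is mathematically unidentifiable from mean-normalized counts — the
baseline shift absorbs any uniform rescaling — so keeping them would
make "correct ploidy" an ill-posed target rather than a hard test. A
configurable fraction of cells (default 10%) is flat diploid regardless
of tree ploidy; these are identifiable only through the ploidy-nearest-2
tie-break, which is exactly how a human analyst resolves a featureless
diploid profile.

Counts are drawn per cell and bin with mean depth_mean · c / ploidy ·
g(gc), where depth_mean = 40 is the expected reads per bin at baseline
(the regime of 0.02x coverage, 200 kb bins, ~100 bp reads) and g an
optional GC bias curve. The default noise law is Poisson: a 200 kb bin
count sums over thousands of short amplicons, so amplification
variability largely averages out and sequencing sampling dominates
(per-bin LRC σ ≈ 0.23 at 40 reads). Negative-binomial overdispersion is
available (``dispersion`` = NB size) for stress tests; at var/mean ≥ 2
the per-cell ploidy evidence shrinks toward the selection noise floor and
ploidy errors appear — which is a property of the data regime, not of
the caller.

What the simulator does *not* model: alignment artifacts, mappability
structure, replication-timing waves, cell-cycle and doublet effects, and
sub-bin breakpoint placement (true breakpoints always fall on bin
edges). Passing benchmarks here therefore shows correctness of the
method's statistics under its own assumptions, not robustness to every
real-data pathology.

## Evaluation metrics

Against per-bin ground truth: (1) summed distance, in bin units, from
each true breakpoint to the nearest inferred one (the full bin count per
true breakpoint when nothing was inferred); (2) w = |inferred| / |true|
breakpoints, ideal 1.0; (3) per-cell MAD, the mean |true − inferred| copy
number over common bins; (4) per-cell average copy number (ACN) and
ΔACN = truth − inferred (overestimated ploidy gives negative ΔACN).
Truth is restricted to the bins and cells that survive preprocessing so
both sides share one coordinate space.

## Benchmark protocol and problem sizes

The packaged benchmark (`cellcna.study`, also behind
`scripts/acceptance.py`) runs, per ancestral ploidy in {2, 3, 4}, ten
replicates of: 100 cells, 4 tumor clones + 10% normal cells, simulated
genome of 8 chromosomes x 30 Mb (1200 bins at 200 kb), depth 40
reads/bin, Poisson noise; pipeline at d = 1, 500 epochs, lr 1e-4, batch
256, CBS α = 0.1 with 200 permutations per test, max copy number 10.
The genome is sized so a replicate finishes in well under a minute on one
CPU while every replicate still carries its full clone structure; CBS
permutations are 200 in the protocol (the library default is 1000)
because p-values only need resolution well below α = 0.1.

## Known limitations

- Per-cell ploidy is only identifiable if the cell's profile is not an
  exact rescaling of a flatter one; for flat cells the caller reports the
  lowest-ploidy consistent interpretation (diploid), by design.
- Even for identifiable profiles, the margin separating the true baseline
  from a rescaled one is carried entirely by odd-copy segments and can be
  a handful of log-likelihood units for weak clones. Residual model
  misfit of similar size is absorbed asymmetrically by denser state
  grids, so a few percent of aneuploid cells in occasional datasets are
  called at a ×3/4-, ×3/2- or ×2-rescaled baseline; the errors cluster by
  clone. Cross-cell ploidy consistency would remove them but the mixture
  is deliberately fit independently per cell.
- The shared-σ Gaussian understates the variance of low-copy segments
  (log-Poisson variance scales with 1/λ), which costs likelihood
  headroom; the ploidy-range guard compensates.
- Segmentation operates on bins; breakpoints inside bins are
  undetectable, and boundary localization can be off by a bin, which the
  distance metric counts.
- The d = 1 code occasionally fails to represent one clone's CNA pattern
  at all (longer training does not recover it), making those breakpoints
  invisible to CBS. The summed breakpoint distance is heavy-tailed as a
  result — one dropped event adds tens of bins — and if the dropped
  event carried a clone's only odd-copy segments, the clone's visible
  profile becomes exactly rescalable and its cells collapse to the
  lower-ploidy interpretation. d = 2 reduces the dropout risk at the
  cost of extra breakpoints.
- The consensus breakpoint rule keeps any boundary at which a single
  cell changes copy number, so residual over-segmentation scales with
  per-cell call noise rather than averaging out.
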