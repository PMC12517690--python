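# Methods

`pulvigrad` implements a multimodal connectopic-gradient pipeline for a small
bilateral subcortical structure (modelled on the pulvinar complex of the
thalamus): voxel-wise feature matrices from three modalities are converted to
affinities, embedded with diffusion maps, projected onto the cortex,
discretised in gradient space, and tested against spatial-autocorrelation
(SA) preserving null models.  Because the method's correctness properties are
what matter, the package ships a synthetic-data module that plants recoverable
structure for every stage; this note records the model, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Feature matrices

Three voxel-by-feature matrices feed the embedding, one per modality:

- **Functional**: Pearson correlation of each voxel's BOLD-like series with
  each cortical parcel's mean series.  Negative correlations are zeroed, each
  row is thresholded at its 90th percentile (linear-interpolation percentile
  computed after zeroing; values strictly below the threshold are zeroed,
  ties kept), values are Fisher r-to-z transformed (|r| ≥ 1 clamped to
  1 − 1e-7 with a warning), and subjects are averaged elementwise.
- **Structural**: voxel-to-parcel streamline (tract-density) counts averaged
  across subjects; no thresholding and no transform — sparsification and
  Fisher z apply to the functional modality only.
- **Receptor coexpression**: a voxel-by-tracer density table, each column
  z-scored over the analysis mask (sample SD, n−1, as everywhere in this
  package).

Voxel-wise SNR maps (temporal SNR for BOLD series, b0-SNR for diffusion
volumes) are per-voxel mean divided by sample SD along the series axis;
zero-SD voxels are flagged undefined, never silently zeroed.

## Diffusion-map embedding

Each feature matrix becomes a symmetric voxel-by-voxel affinity
`A = 1 − cosine distance` between feature rows.  Negative cosine
similarities — possible for signed (z-scored) receptor features — are
rectified to 0 because the diffusion operator requires nonnegative
affinities; the diagonal is set to exactly 1.

With degrees `q_i = Σ_j A_ij` and density-normalisation exponent α (default
0.5, the Fokker-Planck convention that is robust to sampling-density noise),
the anisotropic kernel is `K = A / (q_i^α q_j^α)` and the diffusion operator
is the row-stochastic `M = D⁻¹K`.  Its spectrum is obtained through the
symmetric conjugate `D^{1/2} M D^{-1/2}` (exactly equivalent, numerically
stable).  The trivial constant eigenvector (λ₀ = 1) is dropped; component k
is the k-th nontrivial right eigenvector scaled by `λ_k/(1 − λ_k)` at
diffusion time 0 (the multiscale convention) or `λ_k^t` for t > 0.  Explained
variance of component i is `λ_i / Σ λ_j` over the retained positive
nontrivial eigenvalues.  Signs are made deterministic (first nonzero loading
positive) before any alignment step.  A disconnected affinity graph is an
error listing component sizes, never a silent regularisation.

**Scree elbow.** The number of retained gradients is the point of the
*cumulative* explained-variance curve at maximum perpendicular distance from
the chord joining its first and last points.  The cumulative-curve convention
is the package's own: it reproduces the intended behaviour on reference
screes (e.g. (0.50, 0.15, 0.14, 0.01) → 3; a dominant first gradient → 1),
whereas the same rule on the raw scree collapses to the second point almost
always.  A linear cumulative curve (equal fractions) is degenerate and yields
1 with a warning.

**Alignment.** Gradient signs are indeterminate; right-hemisphere gradients
are flipped to match their left counterparts when their correlation is
negative.  Across datasets/resamples, whole gradient sets are aligned by
orthogonal Procrustes (rotation/reflection, no scaling) before correlation.

## Gradient-weighted projection

A pulvinar gradient g is projected onto the cortex as
`map(p) = mean_v g(v)·F(v, p)` — linear in g.  By default F is the raw
(un-thresholded, pre-Fisher) group connectome: which processing stage enters
the dot product is genuinely open, and the raw connectome keeps the dot
product interpretable as gradient-weighted connectivity; a processed matrix
can be passed instead.  Maps are min-max normalised only for display;
statistics always use unnormalised values.  Left/right maps are averaged
plainly (symmetric functional maps) or after mirror re-indexing of the right
map (structural maps, where ipsilateral connectivity should stack on one
side).

## SA-preserving null models

Correlations between smooth brain maps are anti-conservative under naive
permutation because nearby voxels are exchangeable only in name.  The null
model here permutes a map and restores its SA fingerprint: for each
surrogate, the permuted map is smoothed with a Gaussian distance kernel at 8
log-spaced candidate bandwidths; the target variogram
`γ(h) = ½·mean (y_i − y_j)²` (25 equal-width bins, pairs up to 50% of the
maximum distance, at most 50 000 pairs sampled) is fitted as a *nonnegative*
affine function `β·γ_smoothed + α` of each smoothed map's variogram; the
best-SSE bandwidth wins and the surrogate is
`sqrt(β)·smoothed + sqrt(α)·white noise`, rank-resampled onto the original
values so every order statistic is preserved exactly.

Two numerical choices matter and were fixed after explicit calibration
experiments (type-I error of the resulting test on independent smooth fields
sharing a correlation length):

- the smoothing kernel spans **all** points by default rather than a capped
  neighbour count — a k-nearest cap floors the achievable smoothness and the
  surrogates come out rougher than the data, inflating the test
  (empirically to ≈0.17 at α = 0.05 with k = 100 on 500-point fields);
- the affine fit is **nonnegativity-constrained** (NNLS): unconstrained least
  squares exploits a negative intercept, and reconstructing with |α| then
  injects white noise that destroys the short-lag variogram match.

With both choices the empirical rejection rate sits at the nominal level
(0.045 at α = 0.05 over 200 replicates of 500-point fields) while the naive
permutation test rejects at ≈0.8 on the same pairs.  `k_neighbors` remains
configurable for large problems.

P-values are two-sided on |r| (gradient signs are indeterminate, so the
package reports absolute correlations), use the add-one estimator
`p = (#{|null| ≥ |obs|} + 1)/(n_surrogates + 1)` (never exactly 0, floor
1/(n+1)), and default to 1000 surrogates.  Families of tests are adjusted
with Benjamini-Hochberg step-up FDR (statsmodels backend, verified against a
brute-force implementation).

## Clustering in gradient space

Selected gradients are min-max scaled to [0, 1] per component, concatenated
(within or across modalities), and swept with k-means for k = 2…30
(Euclidean, 10 restarts per k, best by within-cluster sum of squares); the
mean silhouette coefficient over all points selects k, ties going to the
smaller k.  Overlap with atlas nuclei is the Dice coefficient
`2|A∩B|/(|A|+|B|)` for every cluster/nucleus pair, reported per nucleus as
the maximum across clusters.  Silhouettes are computed on all points at the
package's toy scale; a subsampling flag is deliberately out of scope at this
size.

## Reliability

Split-half stability: subjects are randomly assigned to two disjoint,
exhaustive halves (floor split with a warning for odd counts), each half is
group-averaged and embedded, the second embedding is Procrustes-aligned onto
the first, and per-gradient Pearson r is recorded; the median and IQR across
iterations (default 100) are reported alongside the mean, since both
conventions are in use.  Test-retest embeds two acquisitions of the same
connectome and correlates aligned gradients (identity input gives r = 1
exactly).  The SNR confound analysis correlates each gradient with a
voxel-wise SNR map under the SA-corrected permutation test, BH-adjusted
across gradients; undefined-SNR voxels are excluded pairwise with a warning.

## Synthetic data: what it emulates, what it does not

The generators produce: a bilateral ellipsoidal voxel blob (mirrored across
the mid-sagittal plane by negating x) partitioned into contiguous Voronoi
nuclei; cortical parcels on a jittered spherical shell with contiguous
angular network sectors; a parcel-level connectome
`C = Σ_j w_j g_j g_jᵀ + noise` with orthonormal smooth (Gram-Schmidt
polynomial) gradients; a voxel-to-parcel connectome whose profile at voxel v
is a baseline (0.25) plus `Σ_j a_j s_j(v) g_j(p)`, where s_j increases along
planted spatial axis j in mirrored per-hemisphere coordinates and amplitudes
decay geometrically (a₁ = 0.5, ratio 0.6 — mirroring the typical fall-off of
explained variance across successive gradients); latent-factor time series
whose sample correlations converge to a target connectome; negative-binomial
streamline counts (overdispersed, variance μ + φμ²); receptor maps as
loadings on the planted axes; and Gaussian random fields with a
squared-exponential covariance of known correlation length.

The toy scale is ~300 voxels per hemisphere and 100 cortical parcels, sizes
at which every stage runs in seconds while all planted-recovery properties
hold; full 400-parcel runs are supported.  The amplitude decay was calibrated
once so the prescribed recovery property holds — at snr ≥ 10, cosine affinity
plus diffusion embedding of the planted connectome recovers each planted axis
with |r| ≥ 0.9 (in practice ≈1.0) and explained variance follows the planted
order.  One instructive non-goal: at this parcel count, the top-10% row
threshold keeps only 10 entries per voxel, which makes the functional chain's
recovered gradients curved monotone transforms of the planted axes (first
gradient still |r| ≥ 0.9; deeper axes less) and can even disconnect the
affinity graph on noise-free input — a real small-support artefact worth
knowing about, which is why recovery assertions are pinned on the
affinity+embedding core while the sparsified chain is exercised end-to-end in
the pipeline tests.

What passing tests show: the operators are correct (spectral oracle
agreement), planted geometry is recovered, the SA-corrected statistics are
calibrated under the generator's assumptions (stationary Gaussian fields,
isotropic SA), and the pipeline is deterministic given seeds.  What they do
not show: robustness to nonstationary SA, realistic anatomy, registration or
acquisition artefacts, subject heterogeneity beyond additive Gaussian noise,
or tractography biases — none of which the generators attempt to emulate.

## Degenerate inputs and tie-breaks

Constant time series, all-zero feature rows, zero-variance tracers and
constant maps are errors naming the offending voxel/tracer.  An
all-identical-rows affinity yields a degenerate embedding flag.  Silhouette
ties select the smaller k; eigenvector ordering is by descending eigenvalue
with a fixed sign convention; the variogram merges empty bins into occupied
neighbours with a warning.  All generators and every stochastic stage are
pure functions of their seed; pipeline reruns with equal configs are
byte-identical.
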