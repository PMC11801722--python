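# Methods

This note documents the generative model behind the synthetic sessions, the
statistical procedures, the numerical choices, and the limits of what the
synthetic validation can show about real recordings.

## Task and session model

A session emulates free-viewing color-singleton search: eight stimuli on a
rhombus (index 0 at the right horizontal position, counterclockwise), one
target per trial, and three display types — singleton present (one color
oddball), singleton absent, and mixed color (the same oddball stimulus and
flankers in a context where it is not salient). Trials are generated per
(display type × RF content) condition, 40 per condition by default, with the
display order randomly interleaved. Target and singleton positions are
balanced over admissible locations by blocked randomization (tile + shuffle,
with collision swaps that preserve the per-location counts); this mirrors the
stratified designs used in such experiments and guarantees that each
contralateral location has enough trials for 5-class decoding at the default
trial counts.

All units of a session share one RF position (default: the contralateral
horizontal location, index 4). This keeps the per-trial RF-content label
(target / salient distractor / non-salient distractor in RF) well defined at
the session level; pooling units with heterogeneous RFs across sessions is
out of scope of the generator.

## Unit model

Each unit has

- a baseline rate (log-normal, median ≈ 15 spikes/s),
- a visual gain (uniform 1.5–3) applied through a ramp rising 40–90 ms after
  array onset,
- an **archetype** controlling a multiplicative singleton gain applied when
  the singleton occupies the RF in singleton-present displays:
  suppression (×0.7 in 75–300 ms), early-enhancement/late-suppression
  (×1.35 in 25–100 ms, ×0.7 in 125–300 ms), enhancement (×1.3 in 75–300 ms),
  or nonselective (×1). The profiles equal 1 outside 0–300 ms. Default mix:
  35 / 20 / 15 / 30%.
- **additive low-rank location tuning**: the population pattern matrices for
  target and singleton location are W = √N·U·L with U an orthonormal N×d
  basis (d = 5) and L a d×8 loading matrix with orthonormal, zero-mean rows,
  scaled so each per-location pattern has norm 40 spikes/s. The two bases
  share principal angles arccos(overlap) by construction; `overlap` ∈ [0, 1]
  is the single knob for subspace geometry (0 = orthogonal, 1 = identical).

The trial rate is
`max(0, baseline + (baseline·visual_gain(t)·rf_gain(t) − baseline + (w_target[p_t] + w_singleton[p_s])·ramp(t))·e^{−κs})`,
and spikes are drawn as an inhomogeneous Poisson process on a 1-ms grid.

Two deliberate modeling choices:

1. The location drive is *additive*, not multiplicative. A multiplicative
   drive would scale each unit's tuning by its baseline, so the population
   patterns would span `diag(baseline)·U` rather than `U` — the planted
   principal-angle geometry would no longer be exactly recoverable from
   noiseless rates. With the additive drive, the planted covariance
   (`synth.planted_covariance`) is exactly rank-d per context and the
   recovered principal angles match `arccos(overlap)` to machine precision.
2. The RF-singleton gain is an RF-content effect, not location coding, and is
   therefore excluded from the planted location-geometry ground truth. Two
   residual couplings remain in the full rate model and are features, not
   bugs: (a) the singleton≠target exclusion leaks −1/7 of each context's
   pattern into the other's condition means (tilting measured angles by
   ≈ atan(1/7) ≈ 8° per context at overlap 0), and (b) the RF gain adds an
   RF-locked rate component. Real search data contain both couplings.

## Behavior model

The task literature reports search-time and saccade statistics but no
generative behavioral model, so the generator defines one: first-saccade
latency is log-normal (median 185 ms); the first saccade goes to the target
with probability 0.55, to the singleton with probability 0.015 (matching the
strong avoidance observed in trained animals; a `uniform` policy samples all
8 positions equally for chance calibration), otherwise to a random
distractor. Search time is log-normal (median 350 ms, ×1.12 in singleton-
absent displays, σ_log = 0.35) with its location parameter decreased by
0.25·s, where s ~ N(0,1) is a per-trial latent state that also multiplies
distractor-evoked (not target-evoked) firing by e^(−0.15·s). This single
latent state is what plants the fast/slow median-split effect: trials with
more suppressed distractor responses are faster, so fast-vs-slow modulation
indices are negative in expectation.

Eye traces are sampled at 120 Hz (the temporal resolution of the emulated
tracking system): Gaussian fixational jitter (SD 0.02°) plus logistic
saccade displacements with a 10–90% rise time of 15 + 2·amplitude ms, so
peak velocity exceeds the 50°/s detection threshold for any amplitude ≥ 1°.

## Statistical procedures and numerical choices

- **Windows** are half-open `[a, b)` ms except the subspace window, which is
  inclusive `[150, 200]` so that 5 locations × 51 time points give the
  255-row condition matrix. Array onset is t = 0.
- **Spike density**: 1-ms binning convolved with a truncated Gaussian
  (σ = 10 ms, ±4σ, no edge renormalization); the time integral equals the
  spike count up to truncation error. Smoothing is linear in the spike set.
- **Saccade detection**: central-difference velocities on the raw 120-Hz
  samples, no extra filtering; events are suprathreshold (>50°/s) segments
  merged across ≤10-ms gaps, kept if ≥8 ms long and displaced ≥0.4°
  (Euclidean start-to-end with one-sample padding). Merge gap and minimum
  duration are config; the source procedures leave them unspecified.
- **AUROC** uses the criterion-sweep construction (criteria from below zero
  to the maximum count) whose trapezoidal area equals the Mann–Whitney
  statistic with ties counted ½ — asserted against exhaustive pair
  enumeration. Per-unit nulls permute condition labels jointly across time
  bins (500 shuffles); the population null draws one shuffle per unit and
  averages (1,000 draws); two-sided rank p-values are corrected across time
  bins by Benjamini–Hochberg at q = 0.05.
- **Effect size** for rank tests is r = z/√n.
- **ω² PEV** allows negative values (unbiased estimator, not clipped);
  degenerate windows (zero total variance) return 0; levels with fewer than
  2 trials are dropped with a warning. The permutation z-score uses 200
  label shuffles; z is NaN where the null SD is 0.
- **Latency**: one-sample t per 5-ms bin, Bonferroni over the bins of the
  0–300 ms analysis window (family size configurable), latency = left edge
  of the first run of ≥5 consecutive significant bins. Cluster latencies are
  computed across units.
- **Profile clustering**: two-sample t per 1-ms bin; units need a run of
  ≥10 consecutive bins at p < 0.05 (uncorrected — this is an inclusion
  screen, not an inference) and must not differ between conditions during
  the −150–0 ms baseline at α = 0.1. Graph: K nearest neighbors (Euclidean),
  Jaccard weights on shared neighbor sets, Louvain at resolution 1.0 with a
  fixed seed; communities smaller than 3 are merged into the nearest
  centroid. Identical-profile inputs are declared a single cluster up front
  (neighbor sets are arbitrary there).
- **Decoding**: linear SVM (C = 1; the cost parameter is unspecified in the
  source procedures), 5-fold stratified CV. Min–max scaling is computed once
  per window over all samples and applied to train and test alike — this is
  the documented procedure and leaks range information; `scale_train_only`
  provides the leakage-free variant (default off for fidelity). Shuffle
  nulls cycle over resamples; p is the upper-tail rank. The cluster-based
  permutation test thresholds per-bin one-sample t values at two-sided
  α = 0.05, scores clusters by summed t, and compares against the sign-flip
  max-cluster distribution (1,000 permutations by default).
- **Subspace optimization**: Riemannian gradient ascent on the Stiefel
  manifold (tangent projection, QR retraction, Armijo backtracking with
  Barzilai–Borwein-style warm start; gradient tolerance 1e−6·(1+|f|), 500
  iterations, PC initialization plus random restarts, best objective kept;
  the line search guarantees a non-decreasing objective). The orthogonal
  pair is a single N×2d frame, so mutual orthogonality is structural. The
  exclusive problems use an exterior quadratic penalty with μ-continuation
  (10²…10⁹) aimed at v − 1e−4, so the returned point satisfies the cap
  itself; feasibility is verified post hoc and a rank-based test detects
  genuinely infeasible inputs (minimum achievable limit variance > v). The
  shared subspace is computed in closed form (top-d eigenvectors of the
  summed normalized covariances projected into the exclusives' orthogonal
  complement). Normalized-variance denominators are the top-d eigenvalue
  sums of each context's own covariance. Covariances come from condition
  means (the 255×N matrix), not single trials; single trials enter only at
  projected decoding, where the pipeline fits Q on the full condition means
  (in-sample; a cross-validated variant would fit Q per training fold and is
  left to the caller via `projected_decoding`'s explicit Q argument).
- **Median split**: computed within each display type (search-time
  distributions differ across displays; a pooled option exists), stable sort
  by search time with ties broken by trial order — tied-at-median trials are
  assigned deterministically and group sizes differ by at most 1.

## Problem sizes

Default library parameters follow the documented procedures (K = 40, d = 5,
v = 1%, 5 folds, 50 resamples, 500/200/1,000 shuffles). The analysis drivers
and the validation suites use 24–100 units, 12–80 trials per condition,
100–800 shuffles, and 60–300 null simulations — sizes chosen so every
statistical property under test (chance levels within ±1%, FDR/FWER bounds,
recovery indices) is measured with standard error comfortably inside its
acceptance band.

## What the synthetic validation does and does not show

Passing tests demonstrate that the statistics are implemented correctly
(oracle equivalences), that the inference procedures control their error
rates (FDR ≤ 0.06, cluster FWER ≤ 0.06 under nulls), and that every planted
structure — archetype clusters, subspace overlap, behavioral coupling — is
recovered by the corresponding analysis. They do not certify performance on
real recordings: the generator omits noise correlations between units
(pseudo-populations are built as in the source procedures, which also
discard them), non-Poisson spiking, RF heterogeneity within a session,
saccade-locked rate modulations, and adaptation across trials. Quantities
reported from real monkey data (suppression percentages, empirical subspace
variances, areal latency differences) are reproduced only as qualitative
patterns here.

Known limitations: at overlap = 1 the orthogonal-pair objective is
degenerate (any split of the common subspace is optimal), so cross-projected
alignment jumps rather than approaching 1 smoothly; the full spike pipeline
recovers archetype clusters only coarsely at realistic effect sizes (the
suppression and biphasic templates share their late segment), so the
clustering recovery criterion is evaluated on template-plus-noise profiles
with separation well above noise, as its planted-partition construction
prescribes.
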