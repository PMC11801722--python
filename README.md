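# popsaliency

Analysis pipeline for how neural populations encode search targets and
salient-but-irrelevant distractors, exercised end-to-end on a synthetic
spike-train generator with planted ground truth.

During color-singleton visual search, a conspicuous distractor competes with
the target on the attentional priority map. Two population-level questions
drive this package: *how* is the singleton encoded at the level of single
units (suppression, enhancement, or both, in distinct subpopulations?), and
*where* does its location live in neural state space relative to the target's
location — in an orthogonal subspace (no interference) or a shared one?

The package implements, as reusable library code plus numbered analysis
drivers:

- **Synthetic sessions** (`synth`): an 8-stimulus search array with
  singleton-present / singleton-absent / mixed-color displays;
  inhomogeneous-Poisson units with archetypal singleton responses
  (suppression, early-enhancement-late-suppression, enhancement,
  nonselective), low-rank location tuning whose target/singleton pattern
  subspaces have planted principal angles `arccos(overlap)`, eye traces, and
  search times coupled to distractor-evoked firing.
- **Preprocessing** (`preprocess`): velocity/amplitude saccade detection
  (50°/s, 0.4°), Gaussian spike densities (σ = 10 ms), across-condition max
  normalization (40–200 ms), a paired-*t* visual-responsiveness screen, and
  contrast-based trial selection (first saccade away from the RF, ≥10 trials
  per condition).
- **Unit selectivity** (`selectivity`): modulation index
  (FR₁−FR₂)/(FR₁+FR₂), rank effect size r = z/√n, time-resolved AUROC via
  the criterion sweep with per-unit shuffle nulls, a population permutation
  test with Benjamini–Hochberg FDR over time, difference latencies (first of
  5 consecutive significant 5-ms bins, Bonferroni), and ω² percent explained
  variance, ω² = (SS_between − df·MSE)/(SS_total + MSE), z-scored against 200
  label shuffles, with target/singleton/mixed/nonselective classification at
  z > 1.645 in 150–200 ms.
- **Profile clustering** (`clustering`): per-unit t-value selectivity time
  courses, then k-nearest-neighbor graph (Euclidean, K = 40), Jaccard
  shared-neighbor edge weights, Louvain modularity maximization — the number
  of clusters is emergent.
- **Population decoding** (`decoding`): pseudo-populations from stratified
  trial resampling (10 trials/condition, 50 resamples), linear SVM with
  5-fold stratified CV and joint 0–1 scaling, 500-shuffle nulls, and a
  two-sided cluster-based permutation test over time windows (50 ms / 10 ms).
- **Subspace geometry** (`subspace`, `stiefel`): from the 255×N
  location-by-time condition matrix (5 locations × 51 ms, 150–200 ms),
  Riemannian optimization on the Stiefel manifold finds (i) mutually
  orthogonal target/singleton subspaces maximizing
  Tr(QᵀCQ)/Σᵢ≤d λᵢ summed over contexts, (ii) exclusive subspaces capping the
  other context's normalized variance at v = 1%, and (iii) the shared
  subspace in the exclusives' orthogonal complement; alignment indices,
  projected-activity decoding, and per-unit weights (row norms of Q) follow.
- **Behavior** (`behavior`): first-saccade rates against the 12.5%
  random-search chance, search-time comparisons, and the fast/slow median
  split linking distractor suppression to search speed.
- **Pipeline & CLI** (`pipeline`, `cli`): `popsaliency simulate|run|decode|subspace`
  orchestrates all stages with a serialized, hashed config and per-stage
  tables plus `report.md`.

## Worked example

```bash
python analysis/01_simulate.py   # reference session, 100 units, overlap 0.5
python analysis/06_subspaces.py  # subspace geometry on that generator
```

prints (seed 4, overlap 0.5):

```
alignment indices (basis | context):
  orth_target|target: 0.939
  orth_target|singleton: 0.066
  orth_singleton|singleton: 0.962
  excl_target|target: 0.845
  excl_target|singleton: 0.010
  shared|target: 0.294
  shared|singleton: 0.296
shared-subspace weights across selectivity classes: F=1.75, p=0.16
cross-projected alignment vs planted overlap:
  overlap 0.00 -> -0.000
  overlap 0.50 -> 0.067
  overlap 1.00 -> 1.000
```

Read: the orthogonal target subspace captures 94% of target-location
variance while leaking 7% of singleton variance; the target-exclusive
subspace keeps singleton variance at exactly the 1% cap while still
capturing 85% of target variance; the shared subspace (orthogonal to both
exclusives) captures ~30% of each context — the planted overlap of 0.5 means
the two representations are genuinely non-orthogonal, and the measured
cross-projected alignment rises monotonically with the planted overlap.
Shared-subspace weights do not differ across selectivity classes (one-way
ANOVA p = 0.16): the shared code is a weighted mix of all units, not a
dedicated subpopulation.

`analysis/07_behavior.py` similarly reports singleton avoidance (first
saccade to singleton 0.8% vs 12.5% random-search chance, chi-squared
p = 4.6e-08) and negative fast-vs-slow modulation indices (−0.034 for the
singleton in RF): trials with more suppressed distractor responses end
faster.

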