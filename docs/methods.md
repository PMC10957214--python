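# Methods

This note documents the models, estimators and numerical choices behind
`thermofc`, what the synthetic generator does and does not emulate, and the
known limits of the approach.

## Data model and conventions

The unit of analysis is one imaging session (acquisition): an `N × T` matrix
of ROI cerebral-blood-volume signals at sampling rate `fs`, with optional
tissue-motion reference, plus animal id and thermal condition (constant
15/25/35 °C floors or cool/warm, fast/slow, up/down ramps). The canonical
ROI order is the atlas numbering of the reference coronal plane — S1HLL,
M1L, M2L, CgL, CgR, M2R, M1R, S1HLR, HyThL, HyThR — with network groups
somatomotor (S1HL + M1 + M2, both sides), cingulate and hypothalamus.
Symmetric matrices are vectorized in row-major upper-triangle order (with
diagonal: 55 elements for N = 10; without: 45), fixed forever so files and
centroids are interchangeable across runs. Frames are 0-based; epochs are
half-open `[start, start + length)`. Symmetry is enforced to 1e−10 and
positive semidefiniteness to 1e−8.

## Signal conditioning

1. **Artifact detection.** Head and grooming movements corrupt awake fUS
   frames with short high-amplitude bursts across all ROIs and a spike in
   tissue-motion energy. A frame is flagged when the robust z-score
   (median/MAD, MAD scaled by 1.4826) of the motion reference exceeds 3, or
   the robust z-score of the *log* mean absolute ROI deviation from a
   per-ROI rolling-median baseline (window 25 frames) exceeds 3. The rolling
   baseline makes the statistic sensitive to impulsive bursts but not to
   slow hemodynamic excursions, and the log transform symmetrizes the null
   distribution of the across-ROI mean of absolute deviations, whose raw
   right skew would otherwise produce a few percent false positives at the
   z = 3 cutoff. Thresholds (3.0/3.0) and the window are configurable.
2. **Epoch extraction.** Maximal runs of clean frames shorter than 50 frames
   are discarded entirely; surviving runs are concatenated. Sessions with no
   surviving run are reported as discarded, never silently dropped.
3. **Low-pass filtering** of the concatenated series: 4th-order Butterworth,
   0.1 Hz cutoff, applied forward–backward (zero phase, so no lag distorts
   correlations). By default the concatenated series is filtered as one
   piece, the convention in awake-imaging workflows, despite the seams this
   spans; `filter_per_epoch` offers the per-epoch alternative. Note that a Butterworth response is not
   a projection: re-filtering an already filtered signal re-attenuates
   near-cutoff content by a few percent, so the conditioning chain is only
   approximately idempotent (detrending, an exact least-squares projection,
   is exactly idempotent).
4. **Detrending**: per-ROI least-squares polynomial of order 3, removing
   slow drifts of probe coupling and physiology.
5. **Optional smoothing** (centered moving average; off by default) and
   per-ROI z-scoring with sample (1/(T−1)) variance.
6. **Global-signal handling.** `remove_global_component` subtracts the best
   rank-1 approximation of the row-centered ROI × time matrix (first
   singular component). It is implemented and fully tested but **off by
   default**: at 10-ROI resolution the first singular vector is dominated by
   genuine connectivity structure — in strongly coupled states it *is* the
   somatomotor/cingulate-versus-hypothalamus pattern — so removing it per
   session biases every downstream connectivity estimate and destroys the
   very states the dynamic analysis seeks (measured on synthetic cohorts:
   truth-label state patterns drop from ≈0.92 to ≈0.5 correlation with their
   templates when removal is on). Global suppression belongs at the pixel
   level, upstream of the ROI signals this package ingests, where the first
   component is the brain-wide physiological mode.

## Static functional connectivity

Per-session Pearson matrices are computed on the conditioned signals; the
estimator is checked against the direct sums-of-products formula to 1e−12.
Edge-wise condition contrasts are linear mixed models on Fisher-transformed
correlations (`z = atanh(r)`, `r` clipped at 1 − 1e−7):
`z ~ condition + (1 | animal)`, fitted by REML, handling repeated sessions
per animal. The condition effect is a Wald test; its reference distribution
is `t` with `N − g − (p − 1)` degrees of freedom (observations minus animals
minus non-intercept fixed effects) rather than the asymptotic normal, which
is measurably anticonservative at cohort-scale designs (null rejection 0.085
versus 0.052 at nominal 0.05 with 6 animals × 4 sessions); the normal
reference remains available (`reference="normal"`). Boundary fits (zero
estimated animal variance) fall back to OLS with a logged flag — in that
limit the test coincides exactly with a two-sample t-test. Shapiro–Wilk
p-values on residuals are reported per edge but never used to drop edges.
BH correction is applied over the family of testable edges within one
condition pair (45 when complete; families are not pooled across pairs),
with the canonical step-up rule (reject iff adjusted p ≤ q, q = 0.05).

## Dynamic functional connectivity

Per-session z-scored signals (sample variance, so the identity below is
exact) yield per-frame cofluctuation vectors `C_ij(t) = z_i(t) z_j(t)`,
`i ≤ j`. The package maintains the exact identity
`r_ij = Σ_t C_ij(t) / (T − 1)` for every session (tested to 1e−10).
Z-scoring is per session before cohort concatenation, removing session-level
gain differences.

**Outlier removal.** A frame's score is the z-scored mean L1 distance to all
other frames; frames with score > 3 are removed in a single pass (sample
standard deviation). The mean distances are computed per coordinate from
sorted prefix sums in O(L·T log T) — for a sorted column `s` with prefix
sums `P`, the element of rank `r` contributes
`s_r (2(r+1) − T) − 2 P_{r+1} + P_T` — and the result is verified against
the O(T²) brute force.

**Clustering.** L1-distance k-means: Lloyd alternation with cityblock
assignment and coordinate-wise-median centroid update (the L1 minimizer),
which makes the objective non-increasing; convergence on unchanged
assignments, max 300 iterations. Each restart initializes centroids at K
distinct data points drawn uniformly (per-restart RNG streams spawned from
the master seed); the run with the lowest total within-cluster L1 distance
wins; 500 restarts by default. An emptied cluster is re-seeded at the point
farthest (L1) from its current centroid. K = 7 by default.

**Model selection.** The Duda–Hart criterion: for each K, every cluster is
tentatively split in two (squared-error 2-means) and the ratio
`Je(2)/Je(1)` is compared with
`1 − 2/(πd) − z_α √(2 (1 − 8/(π²d)) / (n d))` (d = 55, α = 0.05 by
default); the split count is the number of clusters below the critical
value, and the selected K is the smallest whose split count is zero and
stays zero through `k_max`. Clusters smaller than 2d frames are exempted
from the test (reported) to avoid degenerate statistics.

**Occurrence statistics.** Per-session fractions of retained frames per
state, reported with states ranked by pooled occurrence (ties broken by
centroid L1 norm). Condition effects per state use
`rate ~ condition + (1 | animal)` with a joint Wald omnibus on the condition
levels referred to `F(q, N − g − q)`. Omnibus p-values are BH-adjusted
across the K states — without family-level control the probability of at
least one false state flag across 7 states is ≈ 30% per cohort by
construction — and pairwise condition contrasts (BH within state at FDR
0.05) are computed only for flagged states. An animal × state composition
table with a descriptive chi-square accompanies the model (homogeneity
diagnostic, no gating).

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the reference
study conditions for all benchmarks.

- **States**: seven correlation templates built from factor loadings
  (guaranteed positive definite, unit diagonal): a weak state (all |r| ≤
  0.15), three somatomotor/cingulate-coupled, hypothalamus-anticorrelated
  states (mean within-SM–Cg r ≥ 0.6, mean SM↔hypothalamus r ≤ −0.3)
  distinguished by uniform coupling, an S1-led gradient, and a lateralized
  contrast; a cingulate-decoupled state that also carries the
  SM–hypothalamus dichotomy; and two further states (cingulate–hypothalamic
  coupling with SM suppression; a left-lateralized state). The two
  unconstrained states were deliberately given strong distinct signatures:
  the generator's purpose is parameter recovery, which requires the seven
  default states to be mutually identifiable.
- **Dynamics**: a sticky first-order Markov chain
  (`P = s·I + (1 − s)·1πᵀ`, stationarity π by construction; s = 0.95, so
  the expected dwell is 20 frames = 8 s at 2.5 Hz). Per-frame innovations
  are drawn from the active template and AR(1)-smoothed
  (`x_t = a x_{t−1} + √(1−a²) e_t`, a = 0.9), band-limiting the spectrum
  while preserving unit marginal variance.
- **Occupancy**: per-condition stationary vectors (the weak state dominates
  everywhere, peaks at 25 °C; the dichotomy states are enriched in cool
  fast-down ramps; the cingulate-decoupled state is enriched at constant
  15 °C; warm conditions track neutral). Animal effects are one N(0, 0.3)
  draw per state per animal added to occupancy logits and shared across the
  animal's sessions — exactly the random-intercept structure assumed
  downstream.
- **Nuisance**: cubic drift (0.5 z-units), a shared AR(1) global component
  (0.5), and Poisson motion bursts (3 per 1000 frames, length 1–10 frames)
  that multiply the signal deviations by 10 and spike the motion reference;
  the motion baseline is concentrated near-Gaussian, as expected for an
  energy aggregated over many pixels. Signals are mapped to a positive
  CBV-like scale (100 ± 5 per z-unit). Everything is reproducible from one
  seed; per-session ground truth (state sequence, artifact mask, realized
  occupancy, animal effects) is recorded.
- `simulate_state_blobs` additionally produces *dwell-averaged* cofluctuation
  patterns (template vectors plus isotropic sd-0.12 jitter, the regime of
  long dwells), used to validate cluster-number selection where
  well-separated groups are the relevant regime.

**What the generator does not emulate**: hemodynamic response convolution,
ultrasound physics and speckle, pixel-level structure (so no true
pixel-level global mode), breathing/cardiac physiology, non-Markovian state
durations, and artifact morphology beyond uniform multiplicative bursts.
Passing benchmarks therefore demonstrate correctness of the estimators and
statistics under a faithful covariance/switching structure, not robustness
to every physiological confound of real fUS data.

## Benchmarks, problem sizes and a known limitation

The test suite and `scripts/acceptance.py` use reduced but statistically
meaningful sizes chosen for single-CPU runs: 1000 replicates for mixed-model
type-I error (measured ≈ 0.05), 50 cohorts (6 animals × 3 sessions × 3
conditions) for the null occurrence pipeline (≥ 90% of cohorts with zero
flags), 50 cohorts for planted Δoccupancy = 0.15 sign recovery (≈ 100%
detected), 20 runs for Duda–Hart K selection on high-separation patterns
(true K = 7 selected in ≈ 90%), and full-pipeline cohorts of 6 animals for
scrubbing (sensitivity ≈ 1.0, false positives ≈ 0.2%) and state recovery.
Clustering benchmarks use 12–15 restarts, which empirically reach the same
objective as larger restart counts on these sizes; the library default
remains 500.

**Known limitation — single-frame state recovery.** With K = 7 k-means on
*single-frame* cofluctuation vectors, Hungarian-aligned centroid-to-template
correlations on default cohorts reach ≈ 0.9–1.0 for the strongly expressed
states but only ≈ 0.4–0.8 across all seven (acceptance reports the measured
minimum and mean). Two structural causes, verified experimentally: (i) a
single frame's cofluctuation has per-coordinate noise of standard deviation
≥ 1 while between-state differences are at most ≈ 0.6 per edge, so the
k-medians objective attains its optimum at a partly amplitude-based
partition rather than the generating partition (independent restarts
converge to one objective whose label agreement with ground truth is ≈ 0.26
even on iid, balanced, nuisance-free frames; seeding Lloyd at the true
centroids converges to a *worse* objective); and (ii) the default dwell time
(8 s) is comparable to the 0.1 Hz filter width, so many retained frames are
blends of adjacent states, capping even the truth-labeled pattern ceiling
near 0.9. This mirrors the method's behavior on real recordings — a dominant
low-amplitude state (the most frequent state occupies ≈ 53% of frames in
the default cohorts) plus strongly patterned clusters — and is a property
of per-frame cofluctuation clustering, not of this implementation.
Occupancy-level inference (the occurrence-rate statistics) is unaffected and
fully calibrated.
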