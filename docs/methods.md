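# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `eegstates`.

## Signal model of the synthetic generator

Real resting-state EEG is not available to ship, so validation rests on a
generator whose ground truth is exact. Its assumptions:

* **Brain states are binary phase topographies.** A state is a unit vector
  over channels with entries ±1/√n, positive on one spatially contiguous
  electrode subset and negative on the other (contiguity is enforced on a
  channel adjacency graph: a ring for small montages, a Delaunay-triangulated
  spherical-cap layout for dense ones). Channel c carries
  `|w_c|·cos(2πf t + π·[w_c<0])` — an alpha carrier (default f = 10 Hz)
  whose phase flips by π on the negative subset — plus white Gaussian noise
  of standard deviation `noise_sd` (default 0.5, in weight units). Equal
  magnitudes are deliberate: the leading eigenvector of a cosine
  phase-difference matrix recovers the *sign pattern* of relative phases, so
  an equal-magnitude topography coincides with what the analysis can in
  principle recover; with unequal magnitudes the planted vector and the
  recoverable vector would differ by construction.
* **Switching is first-order Markov with zero diagonal.** The conditional
  matrix is a random walk on symmetric edge weights (hence reversible, zero
  entropy production) multiplied by `exp(±3a)` along a cyclic direction;
  the asymmetry knob `a ∈ [0, 1]` drives a probability current. The analytic
  entropy production of the chain,
  `H = Σ π_i P_ij log2(π_i P_ij / (π_j P_ji))` bits per transition, is
  available in closed form, and `ground_truth_with_entropy` root-finds `a`
  (Brent's method) to hit a requested H exactly. With two states and zero
  diagonal the chain strictly alternates and H ≡ 0.
* **Dwell times are truncated-geometric.** Visit durations in samples follow
  a geometric-ratio law truncated to 50–500 ms with mean 125 ms (defaults);
  the ratio is solved numerically so the truncated mean matches the request.
  Memorylessness within the truncation keeps the visit process first-order
  Markov.
* **Bad channels** (0–12 per subject) are replaced by pure noise, emulating
  interrupted electrodes, and recorded in the sidecar ground truth.

Not modeled: eye blinks, muscle and line artifacts, 1/f background, volume
conduction, genuine between-subject variability of the switching process
within a group. Passing tests therefore demonstrate correctness of the
*pipeline machinery* under a controlled signal model, not robustness to the
full artifact repertoire of real EEG.

## Preprocessing

Defaults mirror a standard resting-state workflow: Hamming-window FIR
high-pass (passband edge 1 Hz, transition 1 Hz, −6 dB at 0.5 Hz) and
low-pass (edge 40 Hz, transition 10 Hz, −6 dB at 45 Hz), both applied
forward with group-delay compensation (symmetric taps in "same"-mode
convolution — exactly zero-phase); average reference computed over good
channels only but subtracted from all; a 6th-order Butterworth band-pass
(8–12 Hz) run forward–backward with `sosfiltfilt` (zero net phase, squared
magnitude — the "order 3 per pass" reading is available via the `order`
argument); decimation to 100 Hz (alpha band-limiting provides
anti-aliasing); per-channel linear detrend. The first and last second of
every contiguous segment are excluded from phase analysis (Hilbert and
filter edge transients).

## Phase dynamics

The cosine phase-difference matrix is rank 2 (`M = ccᵀ + ssᵀ` with
`c = cos φ`, `s = sin φ`), so leading eigenvectors are obtained from the
2×2 Gram problem vectorized over all timepoints; a dense `eigh` path exists
for arbitrary symmetric matrices and the two agree to 1e-6. Eigenvector
sign is canonicalized (element mean ≤ 0) purely for reproducible
serialization.

Polarity-invariant k-means uses distance `1 − |v·c|`, k-means++-style
seeding under the same metric, centroid update by the dominant eigenvector
of the cluster scatter, convergence on unchanged assignments (cap 500
iterations), the best of 20 restarts by total within-cluster distance, and
re-seeds empty clusters from the worst-fitted vector. No temporal
smoothness penalty is applied. Ties in state assignment break toward the
more dominant state.

Patching strata use the same number of clusters as the final model, keeping
donor strata aligned with the states. Fallbacks when no donor exists (the
electrode is bad in all other group members): the subject's own same-cluster
values at that electrode, then the nearest good electrode's same-cluster
ensemble; both are logged. Patching never alters good-channel values.

## Entropy production

Log base 2 throughout (results in bits). The +1 increment guarantees finite
log-ratios; observed and surrogate tables pass through the identical
counting-and-increment estimator, so the symmetric-floor subtraction also
cancels the increment's effect. Surrogate chains are driven by the
row-conditional matrix of the incremented table, start from the empirical
visit frequencies, and have exactly as many transitions as the observed
visit sequence ("length" is the transition count — dwell times never enter
the estimator). Corrected values are not clipped at zero: clipping would
bias the subject mean upward. Per-subject seeds derive deterministically
from the run seed and subject id.

**Residual bias.** The noise-floor correction removes the finite-length
inflation of the *surrogate* level, but the surrogate generator is the
subject's own empirical table, whose sampled spurious asymmetry — of order
K(K−1)/2 / (2·ln2·L) bits at L transitions — is inherited as if it were
signal. For K = 3 and L = 10⁴ this is ≈ 3·10⁻⁴ bits: negligible against a
single subject's standard deviation (the per-subject estimates land well
within 3σ of truth across the validated grid H ∈ {0, 0.05, 0.2, 0.5}), but
detectable as a positive offset when averaging many replicate subjects of a
perfectly reversible chain, because the bias and the between-replicate
standard error shrink at the same 1/L rate. Users comparing groups are
unaffected to first order (the offset is common to all groups); users
interpreting absolute H near zero should not.

**Variance calibration.** The surrogate distribution's standard deviation
estimates the estimator's sampling error. In the sparse-count regime
(≈ 2500 transitions over 12 states, ~19 counts per cell) it overestimates
the true between-realization spread by ~40%, making the inverse-variance
z-tests conservative; from ≈ 5000 transitions the ratio falls to ~1.1. The
replicate-cohort power-consistency study therefore uses 5000-transition
sequences, where predicted power and empirical rejection rates agree within
a few percentage points.

## Group statistics

Exact inverse-variance formulas; 95% CIs use the conventional 1.96
multiplier, and `ci_to_variance` inverts it to recover variances from
published intervals. The two-sample statistic is the *difference* of
weighted means over the root of summed variances (a sum in the numerator is
not a test statistic), two-sided via `p = 2Φ(−|Z|)`. Hedges' g uses the
Bessel-corrected pooled SD and the small-sample factor `J = 1 − 3/(4N−9)`;
it is computed from subject-level means. Power uses the two-sided
two-sample z-test approximation `power = Φ(d√(n/2) − z_{1−α/2})`, which
yields the design numbers n = 25 (d = 0.8, α = 0.05, power 0.8) and
power ≈ 0.72 at n = 20. No multiple-testing correction is applied by
default, matching the pairwise-test reporting convention; a Bonferroni
option exists in the CLI-free API by adjusting α.

Maturity grouping from bone age (BA) and chronological age (CA), in years:
average for −0.5 ≤ BA−CA ≤ 0.5 (boundaries inclusive), accelerated for
0.5 < BA−CA ≤ 1.5, decelerated for −1.5 ≤ BA−CA < −0.5, excluded beyond.

## Problem sizes used in validation

* Topography recovery: one 128-channel, 300 s, 1000 Hz recording with 4
  planted states (30,000 eigenvectors after downsampling), 20 clustering
  restarts.
* Entropy recovery: 3-state chains, 10⁴ transitions, 1000 surrogates;
  detailed-balance calibration over 50 replicate subjects.
* Replicate cohorts: 100 cohorts of 6 bins × 10 subjects (two age brackets ×
  three maturity groups), 12 states, 5000 transitions and 100 surrogates per
  subject, with the average-maturity bins planted at 0.028 bits against
  0.021 bits in the flanking bins.
* The pipeline-level integration test uses a miniature cohort (16 channels,
  3 states, 10 s at 500 Hz) to keep the default test run fast.

## Known limitations

* **Temporal resolution bounds label recovery.** A zero-phase 8–12 Hz
  band-pass has an impulse-response width of roughly 1/bandwidth ≈ 250 ms.
  When planted dwells average 125 ms, state switches are faster than the
  measurement can localize: with zero noise the per-sample hidden-label
  accuracy saturates near 50–60%, and dwells shorter than ~100 ms can be
  swallowed whole, regardless of the clustering algorithm. With dwells at or
  above ~300 ms (within the generator's supported 50–500 ms range) the same
  pipeline recovers topographies at |cosine| > 0.95 and labels at > 95%
  accuracy, which is what the unit-level recovery tests verify. On real
  data the analysis never claims sample-exact state boundaries; dwell and
  transition statistics inherit this band-limited smoothing.
* The corrected entropy estimator's residual bias and sparse-count variance
  behavior are described above.
* The generator plants identical chains within a bin; real cohorts add
  between-subject heterogeneity that inverse-variance weighting only partly
  models.
* EDF I/O implements the plain 16-bit EDF layout (no EDF+ annotations,
  whole-second records, integer sampling rates).
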