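# eegstates

Brain-state dynamics and entropy production from resting-state EEG.

`eegstates` is for researchers who want to quantify the *time-irreversibility*
of large-scale brain dynamics — a proxy for hierarchical cortical
organization — from multichannel resting-state EEG, and to compare it across
groups (for example, adolescent maturity groups defined by the difference
between bone age and chronological age). It implements the full chain from
raw recordings to group statistics, together with a synthetic-EEG generator
that plants known brain-state Markov dynamics so that every stage can be
validated against ground truth.

## The method

1. **Preprocessing.** Zero-phase FIR high-pass (1 Hz) and low-pass (40 Hz),
   average re-referencing over good channels, 6th-order Butterworth band-pass
   for the alpha band (8–12 Hz) applied forward–backward, downsampling to
   100 Hz, detrend and demean. Noisy epochs are excised by a user-supplied
   mask; excised stretches become continuity breaks that no later stage
   bridges.

2. **Leading-eigenvector dynamics.** The Hilbert transform gives each
   channel's instantaneous phase φ_x(t). At every 10 ms step the phase
   coherence matrix

       PC_xy(t) = cos(φ_x(t) − φ_y(t))

   is summarized by its leading eigenvector V₁(t) (the matrix has rank 2, so
   this is computed in closed form for all timepoints at once). Missing
   ("bad") channel phases are *patched* in two steps: a plain k-means over
   good-channel eigenvectors stratifies timepoints into dynamical clusters,
   and each missing value is filled by sampling a donor phase from other
   subjects of the same group at the same electrode within the same cluster.

3. **Brain states.** Eigenvectors pooled over all subjects are clustered with
   a polarity-invariant k-means (`PolarityInvariantKMeans`, a scikit-learn
   estimator): distance `1 − |v·c|`, centroid update by the dominant
   eigenvector of the cluster scatter. The default is K = 12 states, ranked
   by dominance (share of total time). Every recording becomes a sequence of
   state labels.

4. **Entropy production.** Per subject, state visits are reduced to a table
   of off-diagonal transition counts N_ij; with the +1 increment
   N″_ij = N_ij + 1 and joint probabilities P_ij = N″_ij / Σ N″, entropy
   production is the Kullback–Leibler divergence between forward and
   time-reversed transitions:

       H = Σ_{i≠j} P_ij · log2(P_ij / P_ji)   [bits]

   H = 0 under detailed balance; H > 0 measures the "arrow of time" in state
   switching. Because finite trajectories inflate H, 1000 surrogate Markov
   chains of the same length are simulated from the subject's own table and
   1000 more from its symmetrized table; the mean symmetric-table entropy
   (the noise floor) is subtracted from every asymmetric-table value, and
   the corrected distribution yields the subject's mean H_i and variance σ_i².

5. **Group statistics.** Groups are compared with inverse-variance weighting,

       H̄ = Σ(H_i/σ_i²) / Σ(1/σ_i²),  var(H̄) = 1/Σ(1/σ_i²),

   95% CIs as H̄ ± 1.96·√var(H̄), two-sample z-tests
   Z = (H̄₁−H̄₂)/√(var₁+var₂) with p = 2Φ(−|Z|), Hedges' g effect sizes, and
   the matching two-sample z-test power analysis.

## Worked example

```python
import numpy as np
from eegstates.entropy import entropy_production, table_from_counts, subject_entropy
from eegstates.phase_dynamics import StateSequence
from eegstates.synthetic_data import ground_truth_with_entropy, sample_state_path
from eegstates.pipeline import reference_test_results

# Eq. for H on a tiny hand-checkable table: N12=3, N21=1
t = table_from_counts([[0, 3], [1, 0]])
print(f"H = {entropy_production(t):.4f} bits")

# recover a planted entropy production of 0.2 bits from 10,000 transitions
gt = ground_truth_with_entropy(3, 0.2, seed=1)
path = sample_state_path(gt, 10_000, fs=100, seed=7)
seq = StateSequence(labels=path + 1, segment_id=np.zeros(path.size, dtype=int), K=3)
est = subject_entropy(seq, n_surrogates=1000, seed=11)
print(f"corrected H = {est.H_mean:.4f} ± {est.H_var**0.5:.4f} bits (planted 0.2000)")

# headline group comparisons recomputed from the bundled reference summaries
print(reference_test_results().head(3).to_string(index=False))
```

prints

```
H = 0.3333 bits
corrected H = 0.1862 ± 0.0147 bits (planted 0.2000)
   grouping      group1          group2        Z        p
by_maturity     average     decelerated 2.992269 0.002769
by_maturity     average     accelerated 2.643436 0.008207
     by_bin 12y_average 12y_decelerated 2.582667 0.009804
```

The first line is the exact 1/3-bit value of the two-state example; the
second shows the noise-floor-corrected estimator landing within one standard
deviation of the planted value; the last three rows reproduce the published
maturity-group contrasts (average-maturity adolescents show significantly
higher entropy production than both decelerated and accelerated peers) from
the bundled table of group means and confidence intervals.

A command-line interface covers the full pipeline on cohorts of EDF files:

```bash
eegstates simulate --out-dir scratch/demo --seed 1 --n-per-bin 2 \
    --n-channels 32 --n-states 4 --duration 30 --fs 500
eegstates run-all --cohort scratch/demo/cohort.csv --out-dir scratch/demo_run --seed 1
eegstates stats --states-dir scratch/demo_run
eegstates verify-reference-stats
```

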