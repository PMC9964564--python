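# Methods

## Pipeline

Each trial is a 3D position trace (anteroposterior, mediolateral,
vertical; cm) recorded at 240 Hz for 20 s. Processing order is fixed and
deterministic:

1. **Resampling** to 100 Hz by polyphase anti-aliased FIR filtering
   (ratio 5/12), not naive decimation — the ratio is non-integer and
   plain decimation would alias. Sampling at the analysis rate avoids
   the artificial sample-to-sample collinearity that oversampling
   induces in the nonlinear metrics. Resampling is applied to the
   mean-removed trace (mean restored afterwards) because the polyphase
   branches do not carry exactly unit DC gain; edges are padded by
   linear extension. A 20 s trial maps 4800 → 2000 samples exactly.
2. **High-pass filtering** at 1 Hz: 2nd-order Butterworth run forward
   and backward (zero phase, effective 4th order) per axis, the standard
   movement-science choice because it preserves waveform timing. Two
   passes attenuate a 0.5 Hz component to ≈ 6 % of its amplitude and
   leave 10 Hz within 0.1 %. The residual per-axis sample mean
   (finite-record edge effect) is subtracted so the output is exactly
   centred. The filter is applied to *all* conditions, static and
   dynamic, for cross-condition comparability; restricting it to the
   dynamic tasks is possible by composing the stage functions directly.
3. **Resultant distance**: per-sample Euclidean distance from the
   trial-mean 3D position — a single scalar series per trial, invariant
   to rigid translation of the coordinate frame.
4. **Central trim** to 2000 samples (20 s × 100 Hz covers the whole
   trial; when a record is longer, central trimming discards filter
   transients symmetrically).

## Metrics

**SD** uses the sample (N−1) denominator, the convention in the
movement-variability literature.

**Fuzzy entropy** follows the graded-membership formulation: the N−m
templates of length m with their own mean removed, Chebyshev distances,
membership exp(−dⁿ/r) with gradient n = 2, self-matches excluded,
FE = ln φᵐ − ln φᵐ⁺¹ (natural log). Defaults m = 2, r = 0.2·SD, n = 2.
One point needed a decision: with n > 1 a membership computed on raw
distances is not invariant to amplitude rescaling (the exponent dⁿ/r
retains signal units), so FE of a low-amplitude trial would collapse
toward zero regardless of its structure — contradicting the relative
meaning of a tolerance defined as a multiple of the SD. We therefore
measure template distances on the SD-standardised series with tolerance
r_factor, the practice in the fuzzy-entropy literature; this restores
exact scale equivariance (fe(c·x) = fe(x)), which the test suite
enforces, and leaves any unit-SD series unaffected. The tolerance uses
the SD of the same preprocessed RD series the entropy is computed on,
per trial, never a group-level SD.

**DFA** integrates the mean-subtracted series, partitions the profile
into non-overlapping windows anchored at the start (trailing remainder
discarded — the classic formulation), removes a least-squares linear
trend per window (DFA-1; the order is configurable), and takes F(n) as
the RMS residual over covered samples. α is the unweighted least-squares
slope of log₁₀F vs log₁₀n over 18 log-spaced unique integer window sizes
in [4, N/10] (for N = 2000: 4–200 samples). The window-count default of
18 is a density choice, not a sensitivity: α changes negligibly between
12 and 30 windows. The regression R² is returned with every fit and
reported per trial as QC; trials with R² < 0.9 are flagged, never
dropped. The estimator is calibrated on fractional Gaussian noise: over
20 replicates at N = 2000 the mean fitted α lies within 0.1 of the
generating H for H ∈ {0.3, 0.5, 0.8} (white noise within 0.05 of 0.5).
The small upward bias at H = 0.3 and the ≈ +0.02 bias for white noise
are the known small-window DFA-1 effects; they are inside those bands.

## Synthetic data

The generator emulates the *statistical structure* the metrics see, not
limb physiology (no inverted-pendulum or joint-chain model).

* **Static conditions** (HoS, ARelax, A90): independent per-axis fGn
  scaled to a per-condition noise SD. Defaults follow the observed
  per-condition ordering of hand displacement (0.004, 0.009, 0.011 cm),
  with near-uncorrelated noise (H = 0.5–0.55). Cross-axis correlation is
  not modelled.
* **Dynamic conditions** (UpDown, Circle): a deterministic voluntary
  path — vertical sinusoid of 30 cm peak-to-peak, or a 30 cm-diameter
  circle in the frontal plane — at 0.5 Hz, plus noise (0.027 and
  0.043 cm, H = 0.8). The movement tempo is not documented for the
  protocol; 0.5 Hz is a realistic slow-tracking default chosen to sit
  below the 1 Hz high-pass cutoff so the filter removes the voluntary
  component by design. The generator warns if a requested movement
  frequency reaches the cutoff.
* **fGn** is produced by circulant embedding of the exact fGn
  autocovariance (eigenvalues via FFT; generation fails explicitly if
  the embedding is not positive semi-definite rather than silently
  clipping structure). Signals are exactly Gaussian with the target
  covariance; deterministic given a seed.
* **Study generation**: full factorial participants × conditions ×
  trials (defaults 21 × 5 × 3, matching the study design), with a
  log-normal per-participant multiplier (σ = 0.3) on noise SD to give
  the repeated-measures analysis realistic between-subject spread —
  chosen because the observed between-participant SDs are of the same
  order as the condition means. Optionally the relaxed-stance condition
  is also recorded at Shoulder and Hip sensors with site profiles
  (lower amplitude, higher persistence toward the hip, following the
  reported proximal-distal gradient). All per-trial seeds derive from
  one master seed.

What passing tests on these signals do **not** show: real sway has
cross-axis coupling, non-Gaussian and non-stationary episodes, and an
upstream hardware low-pass (the tracker's adaptive single-pole filter)
that the generator does not emulate. Results on synthetic trials
validate the estimators and the pipeline arithmetic, not physiological
claims.

A structural property worth knowing when interpreting full-pipeline
calibrations: the RD norm is an even function of each centred axis, so
it maps Gaussian autocorrelation ρ approximately to ρ². H-recovery
through the *entire* chain is therefore exact only at H = 0.5 (where the
RD series is i.i.d.); persistent noise keeps α > 0.5 through the chain
but attenuated. The estimator-level calibration (on scalar fGn directly)
is the clean benchmark.

## Statistics

* **Lilliefors screen**: KS distance between the sample ECDF and a
  normal CDF with mean/SD estimated from the sample. Because parameter
  estimation shrinks the null distribution, p-values come from a seeded
  Monte-Carlo null (10 000 standard-normal samples of the same size,
  cached per size; add-one rank estimator) rather than table lookup —
  exact at any n and reproducible. Simulated size at α = 0.05 is
  0.05 ± 0.02.
* **RM-ANOVA**: one-way within-subjects decomposition
  SS_total = SS_subjects + SS_conditions + SS_error,
  F = MS_conditions / MS_error on ((k−1), (k−1)(s−1)) df,
  ηp² = SS_cond/(SS_cond+SS_error). No sphericity correction by default
  (the analysis convention here reports integer df);
  Greenhouse–Geisser is available as a flag. With k = 2 the test reduces
  exactly to the squared paired t.
* **Cells**: the mean of a participant's (typically 3) trial metric
  values per condition — the conventional aggregation. Trial-level
  metrics are retained in the output so this choice is auditable.
  Participants with incomplete condition coverage are excluded with a
  logged warning; the run aborts only if a condition loses everyone.
* **Pairwise comparisons**: paired t per condition pair,
  Bonferroni-corrected by default (Holm or none selectable), α = 0.05.
  A zero-variance difference score invalidates only its own pair.

## Problem sizes and determinism

Simulation-based checks use 20 replicates for calibration and
directional properties (N = 2000 series) and 1000 replicates for test
size (type-I error) checks; study-level integration tests use scaled
designs (2–6 participants, 1–2 trials) since every property involved is
size-invariant. Everything stochastic flows from a single seed:
identical seeds give byte-identical outputs, and the run manifest
records config, seed, version and per-stage counts.

## Known limitations

* No artifact/spike rejection or gap-filling; the reader rejects
  malformed rows rather than imputing.
* No mixed-effects or two-way designs; no effect-size confidence
  intervals.
* DFA fits one scaling region (no crossover detection); the entropy
  family is fuzzy entropy only.
* The simulated hardware chain omits the tracker's built-in adaptive
  low-pass filter, so absolute metric values on real recordings will
  differ from synthetic ones even at matched noise amplitudes.
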