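# Methods

## Signal model and preprocessing

A trial is a surface-EMG recording of one muscle over one kick cycle,
sampled at fs ≥ 1000 Hz (2000 Hz by default).  The conditioning chain is
the conventional linear-envelope recipe:

1. **Offset/drift removal** — linear detrend.
2. **Band-pass 20–450 Hz** — 4th-order Butterworth design applied
   forward–backward (`sosfiltfilt`), i.e. zero phase lag and an effective
   8th-order magnitude response.  The stated "4th-order, zero-phase" is
   read as the design order of each pass; this is the common convention
   but the alternative (2nd-order design, 4th-order effective) is a
   config change away (`band_order`).
3. **Mains notch** — IIR notches (Q = 30) at 50 Hz and its harmonics
   (default 50/100/150 Hz), always applied to raw inputs and skippable
   with `apply_notch: false`.
4. **Linear envelope** — full-wave rectification followed by a zero-phase
   4th-order low-pass at 15 Hz (valid range 10–15 Hz for ballistic
   movements).  Negative filter ringing is clipped at zero so envelopes
   stay valid intensity curves.
5. **Time normalization** — the cycle segment (from an events table, or
   the whole trial) is linearly interpolated onto a fixed grid of 101
   points covering 0–100% of the cycle.  One grid step = 1% of cycle,
   which makes trapezoidal iEMG integrals read directly in
   %·normalized-amplitude units.
6. **Amplitude normalization** — every curve of a subject–muscle–leg trial
   set is divided by the single maximum over all supplied valid trials
   (six by default; `max_norm_trials` restricts to the first m trials when
   a stricter convention is wanted).  The set's peak is exactly 1 and the
   operation is idempotent.

## iEMG and the weighted group difference

iEMG is the trapezoidal area under the normalized envelope, per phase
(P1–P4, split at configurable cycle fractions, default 25/50/75%) and for
the full cycle.  Phase boundaries falling between grid nodes are inserted
by interpolation, so the four phase areas partition the full-cycle area
exactly.  The group statistic is

ΔIEMG = [M_e(1+ω_e) − M_s(1+ω_s)] / [M_e(1+ω_e)],

with M_e, M_s the elite / sub-elite mean iEMG and ω ≥ 0 weighting
coefficients (default 0).  With equal weights the ω cancel and the
statistic reduces to the plain relative difference (M_e − M_s)/M_e; the
two-weight form is kept because it is the only reading under which the
weights are falsifiable at all.  The statistic is scale-invariant and
strictly increasing in M_e.

## Functional representation and FPCA

Curves are expanded in an orthonormal Fourier basis on [0, 100] with three
harmonics (7 basis functions) by penalized least squares with a
second-derivative roughness penalty, λ = e⁻⁷ ≈ 9.1e-4 by default.  Three
harmonics are the smallest basis that can represent the multi-peak
envelopes typical of kicking; "third-order" is interpreted as harmonic
count, not total basis size (a 3-function basis cannot hold two peaks).

The covariance operator of the fitted curves is eigendecomposed in the
coefficient domain using the basis Gram matrix under trapezoidal
quadrature, which makes the decomposition exactly equivalent to a weighted
discrete PCA of the fitted curves (this equivalence is tested to 1e-6 on
random instances).  Conventions:

- covariance is normalized by n (population form), so each eigenvalue
  equals the variance of its score vector and the rank-one identities
  (scores ±‖x‖, envelope deviation = √μ·ξ) hold exactly;
- eigenfunctions satisfy ∫ξ_k² dt = 1, ∫ξ_kξ_m dt = 0 under the same
  quadrature; signs are fixed so the integral of ξ_k over the first
  half-cycle is nonnegative (component signs are otherwise arbitrary);
- scores are trapezoidal projections of the centered fitted curves and
  average exactly zero per component;
- FPCA is pooled across both groups within each muscle–leg channel, so
  group differences appear in the scores, not in separate bases.

**Retention.**  K is the smallest k whose cumulative variance proportion
reaches 85%, then truncated to the leading components with eigenvalue
above 1; at least one component is always retained.  The eigenvalue floor
acts on raw covariance eigenvalues (not a correlation-matrix Kaiser rule).
The cumulative rule is applied first and the floor second; the reverse
order would differ only when a sub-floor component is needed to reach the
cumulative target, which the combined rule resolves in favour of the
floor.  Note that on amplitude-normalized curves (values in [0, 1])
eigenvalues are far below 1, so the floor typically truncates retention to
PC1; the floor is scale-bound and should be lowered (e.g. `ev_floor: 0`)
when working on normalized scales.  Component envelopes are
mean ± c·√μ_k·ξ_k with c = 2 by default; ω_k(t) = √μ_k·ξ_k(t) is the
scaled loading.

**Registration.**  Phase variation is removed with a deliberately simple
one-parameter warp per curve, t → t + a_i·sin(πt/100), which preserves
endpoints and is monotone for |a| < 100/π.  Each a_i minimizes the squared
distance of the warped curve to the evolving cross-sectional mean
(a_i = 0 is always admissible, so total cross-sectional variance never
increases); the procedure iterates to a mean change below 1e-6 or 20
iterations, warning (not failing) on non-convergence.  A known limitation:
when amplitude variance is large relative to phase jitter, the single
warp parameter can absorb amplitude variation into phase (the classic
amplitude–phase ambiguity).  Registration is on by default, and should be
disabled (`register: false`) for data known to be free of phase jitter.

## Inference

- **iEMG screening** — mixed-design repeated-measures ANOVA per
  muscle–leg channel (group between, trial within, balanced designs
  only); the group F is tested against subjects-within-groups and
  partial η² = SS_g/(SS_g + SS_subj) with a CI from inverting the
  noncentral-F CDF.  Shapiro–Wilk runs on within-subject residuals and
  Levene on subject means.
- **PC scores** — Welch t on subject-mean scores per retained component,
  with the raw mean difference and CI, and Hedges' g (Welch variant:
  d = t·√(1/n₁+1/n₂), Satterthwaite df), g = J·d, J = 1 − 3/(4df − 1),
  large-sample CI.  Magnitude labels: trivial < 0.20 ≤ small < 0.60 ≤
  moderate < 1.20 ≤ large < 2.00 ≤ very large < 4.00 ≤ extremely large.
- **Multiplicity** — Benjamini–Hochberg step-up adjustment, applied within
  each comparison family (iEMG screen; PC scores) across channels.
- **Discriminant screening** — greedy forward-with-removal selection on
  Wilks' Λ with partial-F thresholds 3.84 (enter) / 2.71 (remove), the
  classical defaults, both configurable.
- **Sensitivity** — balanced random-intercept model on trial-level scores
  with method-of-moments variance components (residual = within-subject
  MS; subject = (between − within)/k truncated at 0); the group effect is
  estimated and tested on subject means, which is exact in balanced
  designs and avoids iterative fitting entirely.
- **Reliability** — ICC(3,k) = (MS_subjects − MS_error)/MS_subjects from
  the subjects × trials two-way ANOVA; CI from F-ratio bounds;
  SEM = SD(subject means)·√(1 − ICC); CV = 100·SEM/|grand mean|.
  Negative estimates are reported as computed and flagged, not clipped.
  In the pipeline, reliability of PC scores is computed on the uncentered
  projections ∫ξ_k x dt — identical ICC and SEM, but a ratio scale on
  which the CV is meaningful (centered scores have mean ≈ 0).

## Synthetic cohorts

The generator emulates a two-group cross-sectional design: by default 10
subjects per group, 6 trials each, 8 muscles × 2 legs, envelopes on the
101-point grid (raw mode synthesizes 2000 Hz carrier signals).  Curves
follow the same low-rank model the analysis assumes:

x_ij(t) = clip≥0( mean(t) + Σ_k (z_ijk + b_ik + δ_k·1[elite])·ξ_k(t) + ε_ij(t) ),

optionally composed with a sine warp of amplitude a ~ N(0, jitter_sd).

- The mean envelope is a sum of Gaussian bumps at the four phase landmarks
  (12.5/37.5/62.5/87.5% of cycle) over a 0.3 baseline; heights 0.3–0.6
  give realistic multi-peak envelopes that rarely clip at zero.
- Modes are low-harmonic Fourier shapes orthonormalized under the
  trapezoidal inner product, so injected score variances land on the same
  scale as reported eigenvalues.  Arbitrary user modes are accepted and
  checked for orthonormality (tolerance 1e-8).
- Default noise levels: trial-level score SD 1.0 per mode, subject random
  offset SD 0.5, additive white trial noise SD 0.25, phase-jitter SD 1.0
  (% cycle), elite shift δ₁ = 1.  These give within-subject correlations
  and between-group separations of the magnitude seen in trained-athlete
  EMG comparisons (subject-mean effect size ≈ 1.5).
- Raw mode multiplies the envelope by a strictly band-limited (20–450 Hz,
  spectral mask) noise carrier with unit rectified mean, then adds a 50 Hz
  mains sinusoid (amplitude 0.05) and a 0.1 DC offset over a 1.6 s cycle.
- Clipping at zero is a deliberate deviation from the pure linear model:
  envelopes are nonnegative by construction of rectification.

What the generator does **not** emulate: motor-unit physiology, amplitude
non-stationarity within bursts, electrode-lift artefacts, cross-talk
between muscles, or non-sinusoidal phase warps.  Passing validation on
synthetic cohorts therefore demonstrates correctness of the estimators
under the assumed low-rank model, not robustness to every feature of real
recordings.

## Validation choices and problem sizes

- Mode recovery and group-shift power use cohorts of 20 subjects per
  group, 6 trials, one injected mode with unit elite shift, no phase
  jitter (there is no phase variance to remove, so registration is not
  applied); 100 seeded replicates.
- Type-I control uses 10 subjects per group, 4 muscles, no group effect,
  100 replicates.
- The preprocessing-chain recovery compares the six-trial mean of the
  estimated normalized envelopes against the (deterministic) target
  envelope, both max-normalized — matching the analysis convention of
  averaging a subject's valid trials and working on the normalized
  amplitude scale.  Per-trial recovery carries the irreducible ~12–15%
  fluctuation of a 15 Hz-smoothed rectified carrier; averaging six trials
  brings it under 10%.
- The oracle for the eigen decomposition is a weighted SVD of the centered
  curve matrix, run at λ = 1e-12 on a 201-point grid with curves drawn
  inside the basis span, 50 random instances, 1e-6 relative agreement.

## Known limitations

- The conditioning band-pass removes a few percent of rectified carrier
  amplitude near the band edges; absolute envelope amplitudes are
  therefore biased low by ~5–9% before amplitude normalization (which
  cancels the bias).  Absolute-scale users should calibrate against a
  known carrier.
- Single-parameter registration cannot separate amplitude from phase
  variation when amplitude variance dominates (see above).
- The mixed-model path requires balanced trial counts; unbalanced designs
  raise an explicit error rather than silently reweighting.
- The stepwise discriminant screen is a greedy heuristic; it inherits the
  instability of stepwise selection at small n and is intended as a
  screening device, not a classifier.
- ΔIEMG weighting coefficients default to 0 because no principled value is
  available; conclusions should be checked for sensitivity to ω.
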