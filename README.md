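# emgfpca

Functional principal component analysis of cycle-normalized surface-EMG
envelopes, built for comparing muscle-activation waveforms between athlete
groups — e.g. elite vs. sub-elite taekwondo athletes performing roundhouse
kicks, with eight instrumented lower-limb muscles per leg and six valid
kicks per athlete.

Discrete summaries (peak amplitude, integrated EMG) discard how activation
is distributed across a movement cycle.  This package treats each trial's
linear envelope as a function x_i(t) on the 0–100% cycle and decomposes the
cohort's covariance kernel a(s,t) into eigenfunctions:

    ∫ a(s,t) ξ_k(t) dt = μ_k ξ_k(s),      Y_ik = ∫ ξ_k(t) (x_i(t) − x̄(t)) dt

Each eigenfunction ξ_k is a mode of waveform variation, μ_k its variance,
and the per-curve scores Y_ik are scalar features that can be compared
between groups with standard inference.  The pipeline covers:

- **Preprocessing** — drift removal, 20–450 Hz zero-phase band-pass,
  mains-harmonic notch, full-wave rectification, 15 Hz linear envelope,
  time normalization to a 101-point cycle grid, amplitude normalization to
  the maximum across a subject's valid trials.
- **iEMG metrics** — trapezoidal areas per movement phase (P1–P4:
  initiation, horizontal kick, recovery, completion) and the weighted
  relative group difference ΔIEMG = [M_e(1+ω_e) − M_s(1+ω_s)] / [M_e(1+ω_e)].
- **Functional PCA** — penalized third-order Fourier basis (λ = e⁻⁷),
  optional one-parameter continuous registration, pooled eigenanalysis per
  muscle–leg channel, retention by cumulative variance ≥ 85% with an
  eigenvalue floor of 1, and mean ± c·√μ_k·ξ_k component envelopes.
- **Inference** — repeated-measures ANOVA screening of iEMG with partial η²
  and noncentral-F CIs, Welch comparison of subject-mean PC scores, Hedges'
  g with small-sample correction J = 1 − 3/(4df − 1), Cohen's d_z,
  Benjamini–Hochberg FDR control, stepwise discriminant screening on
  Wilks' Λ, and a balanced random-intercept mixed model as a sensitivity
  check on trial-level scores.
- **Reliability** — ICC(3,k) (two-way mixed, consistency, average
  measures) with F-based CIs, SEM and CV.
- **Synthetic cohorts** — a generator with known functional modes, subject
  random effects, trial noise, phase jitter and a controllable group
  effect, so every stage is testable with ground truth.

## Worked example

```python
import emgfpca as ef

params = ef.SimulationParams(
    n_per_group=10, n_trials=6,
    muscles=("gluteus_maximus", "biceps_femoris"), legs=("supporting",),
    n_modes=1, group_effect=1.0, seed=42,
)
cohort = ef.simulate_envelopes(params)
bundle = ef.run_pipeline(cohort.recordings, ef.AnalysisConfig())

pc = bundle.stats[bundle.stats["family"] == "pc"]
print(pc[["muscle", "pc", "mean_diff", "p", "p_adj", "hedges_g", "effect_label"]]
      .round(4).to_string(index=False))
```

```
         muscle  pc  mean_diff      p  p_adj  hedges_g effect_label
 biceps_femoris 1.0     0.2909 0.0029 0.0059    1.5537        large
gluteus_maximus 1.0     0.1314 0.3285 0.3285    0.4302        small
```

The cohort injects a unit elite shift along one functional mode in every
channel.  After pooled FPCA, the comparison of subject-mean PC1 scores
recovers it in the biceps femoris channel (FDR-adjusted p = 0.006, Hedges'
g = 1.55, "large") while the gluteus maximus draw happens to be noisier.
The reliability table for the same run:

```
         muscle  pc  icc_3k  ci_low  ci_high   sem  cv_pct
 biceps_femoris   1   0.423  -0.082    0.740 0.172  10.661
gluteus_maximus   1   0.714   0.464    0.871 0.156   4.705
```

ICC(3,6) here quantifies how repeatable a subject's six trial scores are
once averaged; SEM is in score units and CV is the SEM relative to the
mean of the uncentered projection.

The same analysis runs from the shell:

```bash
emgfpca simulate --params params.yaml --out sim/
emgfpca run --input sim/cohort.csv --out results/
emgfpca report --results results/
```

Stages are also available individually (`preprocess`, `iemg`, `fpca`,
`stats`), each consuming the previous stage's CSV output.

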