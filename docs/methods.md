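# Methods

This note documents the models, parameter choices and numerical decisions
behind `fearcond`, and what the synthetic-data validation does and does not
demonstrate.

## Task schedules

Each phase's schedule is built from a `PhaseConfig` holding the protocol
constants (counts, durations, reinforcement, ITI parameters, run-length
bound). Two decisions were genuinely open:

- **Pseudorandomization.** The constraint is "no more than two identical CS
  types in a row". We rejection-sample uniform shuffles until the constraint
  holds (bounded at 10,000 attempts, then a configuration error). Rejection
  sampling keeps the distribution exactly uniform over the
  constraint-satisfying orderings, which the test suite verifies by
  chi-square against an exhaustively enumerated valid set at small counts.
- **Which CS+ trials are unreinforced** is not fixed by the protocol
  constants; the 8 reinforced positions are drawn uniformly at random, and
  callers can pin specific positions (e.g. to always reinforce trial 1).
- **ITI support.** A raw Gaussian admits implausible or negative intervals;
  draws are truncated to mean ± 3 SD by resampling (support [9, 15] s at the
  defaults), which leaves the mean at 12 s and barely changes the SD. The
  same ITI rule is used in all four phases.
- **Time origin.** Onsets are phase-relative seconds starting at one ITI;
  cross-phase absolute timing is out of scope. Each US begins exactly at its
  CS+ offset.

## Synthetic electrodermal signal

The generator is a descriptive, not biophysical, model of palmar skin
conductance:

```
x(t) = tonic + drift·t + Σ_events A_e · k(t − onset_e) + ε(t)
```

- **Kernel** `k`: unit-peak Bateman (difference of exponentials), τ_rise
  0.75 s, τ_decay 2 s, latency 1 s. These place the response peak ≈ 2.6 s
  after stimulus onset, inside the 1–5 s scoring window, and match the
  canonical phasic-response shape used in SCR deconvolution work. The peak
  location has the closed form t* = latency + ln(τ_d/τ_r)·τ_rτ_d/(τ_d−τ_r),
  which the tests use as an oracle.
- **Amplitudes** `A_e`: zero-inflated log-normal. With probability 0.1 a
  trial is a non-response (0); otherwise `A = exp(μ + b_i + ε)` with subject
  intercept SD 0.35 and trial noise SD 0.30 on the log scale. The log-normal
  plus zero inflation reproduces the right-skew that motivates square-root
  transforming SCR amplitudes. The log-mean μ carries the conditioning
  structure: a differential learning slope of 0.12/trial for CS+ during
  acquisition, an extinction decay of 0.08/trial applied to the CS+ excess
  (floored at zero, so the stimuli converge), a global within-session
  habituation of 0.04/trial, a 0.35 boost on retention CS+ trials 1–2
  (early return of fear), and a decaying US amplitude series
  (exp intercept 0.9 µS, −0.10/trial) for the US-habituation model.
  Intercepts put typical amplitudes at 0.2–0.5 µS.
- **Tonic level** 5 µS (SD 1 across subjects), linear drift with SD
  0.002 µS/s, white measurement noise SD 0.01 µS, native rate 1000 Hz so
  that the 10 ms median window and the 100 Hz downsampling stage are
  exercised non-trivially.
- **Ratings**: a proportional-odds generative model on the 1–5 scale with
  thresholds (−1, 0.5, 2, 3.5), a CS+ effect of 0 / 2.5 / 1.0 (pre-habituation
  / post-acquisition / post-extinction) and subject intercept SD 1 — fear
  ratings rise to the CS+ after acquisition and only partially extinguish.
- **Motion**: a six-parameter random walk (step SD 0.03 mm × motion level;
  rotations scaled by the 50 mm radius) with transient single-volume spikes
  (probability 0.02 × level, 0.6–1.8 mm). Motion levels 3 / 1.5 / 0.5 for
  children / adolescents / adults give the age-graded censoring ordering.
- **Covariates** (SES, US sound level, days between sessions) and
  contingency-awareness probabilities (0.79 / 0.85 / 0.95) are drawn from
  group profiles typical of developmental cohorts of this design.
- **Group sizes** default to 36 / 40 / 44 (children / adolescents / adults).
  By default no group differences in SCR level or retention are planted
  ("default" parameter set); "developmental" adds group offsets, "null"
  removes all conditioning structure (for calibration runs).

Determinism: every artifact is a pure function of (parameters, seed);
per-subject seeds are spawned from one `SeedSequence`.

**What passing tests do and do not show.** The generator matches the
modelling assumptions of the analysis stage (log-normal amplitudes,
random-intercept dependence, proportional odds), so end-to-end recovery
demonstrates the pipeline's correctness, not robustness to real-world
violations: it contains no overlapping-response distortion beyond kernel
tail overlap, no electrode drift artifacts, movement-induced transients,
respiration coupling, or non-proportional odds; recordings are stationary in
noise level. QC flags (flat-line, railing, gaps) replace the visual
inspection a human scorer would do; they are tested on constructed cases
only.

## SCR preprocessing

Stage order is fixed: median filter → band-pass → downsample → per-event
peak → amplitude rules → square root. Numerical choices:

- **Median window**: round(0.010 s × rate) samples, forced odd (+1 if
  even), reflected edges.
- **Band-pass**: first-order Butterworth, 0.03–5 Hz, applied
  forward–backward (zero-phase) so event-relative peak latencies are not
  shifted; the effective magnitude response is the squared single-pass
  response, which the tests check against the analytic closed form. A
  single-pass option exists (`zero_phase=False`).
- **Downsampling**: selection decimation for integer rate ratios (1000→100),
  linear interpolation otherwise. Anti-aliasing is provided by the 5 Hz
  band edge, far below the 50 Hz target Nyquist.
- **Windows**: onset is mapped to the nearest sample at-or-after the event
  onset; baseline [0, 1) s and peak [1, 5) s windows are closed–open in
  samples. Scored values are invariant to the recording's start-time offset.
- **Rules**: raw peaks below 0.01 µS (including negative ones) are set to 0;
  peaks above 5 µS are set missing (`ceiling`); windows that leave the
  recording are missing (`window_out_of_range`). Missing propagates through
  the square root.

The zero-phase band-pass attenuates a Bateman peak by a fixed factor
(≈ 4–5 % at the default kernel); the tests measure this factor on an
isolated event and verify every scored trial equals planted × factor.

## Mixed models

- **Gaussian LMM** (one random intercept): REML estimation with the variance
  ratio λ = τ²/σ² profiled analytically per subject block
  (V_i = σ²(I + λJ)), leaving a one-dimensional bounded optimization —
  deterministic, no stochastic starts. Satterthwaite degrees of freedom are
  computed per coefficient from the REML observed information of (τ², σ²)
  (central differences at steps ~ε^{1/3} and ε^{1/4}); they match lmerTest
  to ~5 decimals on shared test data. At a boundary fit (τ̂² = 0) residual
  degrees of freedom are used and the result is flagged. ML refits are
  available for likelihood comparisons. Treatment coding uses CS− and a
  switchable reference group (adolescents or children); trial is the raw
  1-based index (centering available via the model spec).
- **Retention score**: mean √SCR of CS+ trials 1–2 minus CS− trials 1–2;
  by default a subject needs all four early trials (available-case means are
  an option); ordinary least squares on group with an overall F test.
- **CLMM**: proportional-odds logit with Gaussian subject intercept,
  marginal likelihood by adaptive Gauss–Hermite quadrature (15 nodes
  default; 1 node = Laplace). Each likelihood evaluation locates every
  subject's integrand mode by damped Newton steps (the integrand is
  log-concave) and centers the quadrature grid there. Optimization is
  L-BFGS-B over (θ₁, log threshold increments, β, log σ_b) with fixed
  starting values (marginal cumulative logits, β = 0, σ_b = 1). The
  intercept is absorbed into the thresholds (location identifiability);
  Wald z tests use the observed information with a delta-method
  back-transform; no test is reported on the boundary-constrained σ_b.
  With σ_b fixed at 0 the fit reproduces a plain proportional-odds model to
  ~1e−3 (statsmodels `OrderedModel` is the oracle).
- **Missing data**: row-wise deletion everywhere. No multiple-testing
  correction is applied; every emitted table carries a note saying so.

## Pipeline and problem sizes

`run_all` executes simulate → score → fit → report deterministically; the
default 120-subject, four-phase run (≈ 5.6 h of 1000 Hz signal) completes in
about half a minute on one CPU, and repeated runs write byte-identical
tables. The validation suite uses 1,000 replicates for type-I calibration
(40 subjects × 20 trials each), 200 replicates for effect recovery, 10,000
draws for ITI and amplitude distribution checks, and 50 seeds for the
motion-ordering comparison — sizes at which Monte-Carlo error is small
relative to the tolerances tested.

## Known limitations

- Overlapping responses are scored by windowed trough-to-peak, not by
  deconvolution; closely spaced events bias amplitudes via kernel-tail
  overlap (kept small by the 12 s ITI).
- The LMM supports a single random intercept (no random slopes), matching
  the analysis design it implements.
- The CLMM assumes proportional odds and a logit link; no ordinal-scale
  diagnostics are provided.
- Generator parameters are plausible defaults, not values calibrated to any
  real cohort; absolute effect sizes in synthetic runs should not be read as
  empirical claims.
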