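# Methods

This note documents the models, algorithms and design choices implemented
in `rarmodel`, the parameters that matter, and what the synthetic-data
tests do and do not demonstrate.

## Signal model

Breathing is treated as a quasi-periodic oscillation (~0.25 Hz) whose
breath-by-breath amplitude carries an event-related signal: a brief
cognitive input at each conditioned-stimulus (CS) onset drives a linear
time-invariant (LTI) system whose output adds to the baseline breathing
amplitude. The LTI assumption — time invariance and summation of
overlapping responses — is an approximation: true respiration amplitude is
bounded by residual and total lung capacity, so summation cannot hold for
arbitrarily dense stimulation. With inter-trial intervals of 7–11 s the
approximation is treated as adequate, which is also the regime the
synthetic generator reproduces.

## Preprocessing

1. **Inspiration-onset detection.** The raw trace is mean-centered over
   the entire recording, band-pass filtered 0.01–0.6 Hz (order-1
   bidirectional Butterworth) and median-filtered over 1 s. For bellows
   belts (sharp inspiratory pressure drop) onsets are the negative zero
   crossings of the smoothed trace; for MRI pressure-cushion belts they
   are its local minima (sign change of the first difference, first sample
   of a plateau run). Crossings landing exactly on zero belong to the
   first sample at/after the sign change; onsets closer than 1 s to the
   previously kept one are discarded (matching the median-filter scale).
   Traces shorter than 30 s are rejected.

   The 1-s median filter flattens each valley of a smooth trace into a
   plateau of roughly half the window, so cushion onsets sit up to ~0.3 s
   early relative to the analytic minimum; this is stable and well inside
   the 0.5-s matching tolerance used for detector evaluation.

2. **Per-cycle amplitude.** For each inter-onset interval, amplitude is
   the peak-to-trough range of the *raw* (mean-centered, unfiltered)
   trace — robust, device-agnostic, and monotone in tidal excursion. No
   tidal-volume calibration is attempted.

3. **Interpolation.** Each cycle amplitude is anchored at its cycle's
   inspiration onset and linearly interpolated onto a uniform grid
   (default 10 Hz — ample for a signal band-limited at 2 Hz), with
   constant extension beyond the outermost anchors.

4. **Band-pass.** The amplitude series is filtered 0.01–2 Hz with an
   order-1 bidirectional Butterworth (effective order 2). Forward–backward
   filtering is padded well past the high-pass time constant
   (1/(2π·0.01 Hz) ≈ 16 s) to tame edge transients, and the residual mean
   left by the finite record is subtracted, making the output zero-mean to
   machine precision. Order 1 per pass keeps the roll-off gentle
   (no ringing on slow signals); its measured squared gain is ≈ 0.98 at
   0.25 Hz, ≈ 0.81 at 1 Hz, ≈ 0.17 at 4 Hz (20 Hz sampling).

## Response functions

Both canonical components are gamma functions
`y = A/(θᵏΓ(k))·(t−x₀)^(k−1)·e^−(t−x₀)/θ` with shipped parameters
(`src/rarmodel/data/canonical_rf.yaml`, versioned so alternative RFs can
be supplied):

| component | k | θ (s) | x₀ (s) | peak |
|---|---|---|---|---|
| ER | 2.57010·10⁷ | 3.12410·10⁻⁴ | −8.02434·10³ | 4.91 s |
| LR | 3.41302 | 1.10734 | 7.58288 | 10.25 s |

The ER parameterization is extreme (it is numerically a narrow Gaussian —
mean ≈ 4.91 s, SD ≈ √k·θ ≈ 1.58 s). Naive evaluation overflows, and even
straight log-space evaluation loses ~8 significant digits to cancellation
of O(k log k) terms; for k ≥ 10⁴ the implementation therefore substitutes
Stirling's expansion for log Γ(k), which regroups the log-density into
O(1)-sized terms and is accurate to ~10⁻¹² relative error (verified
against 60-digit arithmetic). The analytic derivative is equally
ill-conditioned, so dER/dt is computed by central finite differences of
the sampled ER.

Basis sets: G1 = {ER}, G2 = {ER, dER}, G3 = {ER, LR}, G4 = {ER, dER, LR};
primed variants are the same shapes delayed by SOA − 3.5 s (US-locked).
Components are sampled on a 20-s support (both decay below 1% of peak by
then) and peak-normalized to |max| = 1 so that GLM betas carry the
response amplitude. The derivative component is *not* orthogonalized
against ER: the G2 score is reconstruction-based and therefore invariant
to any invertible recombination within the span (asserted by a test).

Gamma fitting to a difference waveform uses Nelder–Mead over
(log k, log θ, x₀) with the amplitude profiled out analytically at each
step (objective tolerance 10⁻⁸, 10 000 iterations max; non-convergence is
a warning, not an error). Parameters can trade off against each other;
waveform equivalence, not parameter identity, is the contract.

## GLM inversion and scoring

Design-matrix columns are unit-impulse trains at each condition's CS
onsets (nearest grid sample) convolved with each basis component,
truncated at the data end; estimation is condition-wise (one column set
per condition pooling all its trials, matching the high trial-by-trial
variability of respiration), with a single intercept column modelling the
session baseline. The US is not modelled as a separate input. Betas are
the minimum-norm least-squares solution via the Moore–Penrose
pseudoinverse; rank deficiency warns and never errors.

**Observation operator for the regressors.** The observed series is not
the continuous LTI output: it is that output sampled once per breath
(every ~4 s) and linearly interpolated. Sampling-plus-interpolation acts
as a low-pass (triangle-kernel) operator and attenuates the fast ER
component by roughly 15% — a systematic bias if the regressors are built
from the continuous response. `build_design_matrix` therefore accepts the
breath-onset times and passes each column through the same
sample-and-interpolate operator before filtering; the pipeline supplies
the detected onsets automatically. With this forward model the noiseless
end-to-end pipeline recovers generating betas within ~1%; without it
(`sample_times=None`, the filter-only behaviour) ER/LR betas shrink to
~0.75/0.66 of truth. Both data and regressors receive the identical
0.01–2 Hz zero-phase filter, avoiding filter-induced model mismatch.

Scores: G1/G2 — signed extremum of maximal absolute value of the
reconstructed response in the 2–11 s window (window endpoints inclusive at
grid resolution); G3/G4 — β(LR) − β(ER).

## Peak scoring

Trials are epoched over [0, 11] s from CS onset (11 s is the minimum
inter-onset interval of the reference designs) and baseline-corrected by
the mean over the 4 s before onset (about one respiratory cycle). P1 is
the maximum in 2–11 s — on an all-negative window it returns that
(negative) maximum, keeping the statistic total and continuous; P2 is the
signed extremum of maximal absolute value in 2–11 s; P3 is the mean over
2–7 s. Trial scores aggregate to condition level by the unweighted mean.
Because the response outlasts the inter-trial interval, the previous
trial's late response leaks into the next trial's baseline window; a test
demonstrates on noiseless data that this biases peak scores of CS− trials
by their predecessor's condition while the GLM estimate stays at truth.

## Predictive validity

For a table of per-subject condition scores, the condition indicator
(CS+ = 1, CS− = 0; the coding is immaterial — an affine-invariance test
asserts ΔAIC = 0 under rescaling) is regressed on the scores plus one
intercept per subject, and `AIC = n·ln(RSS/n) + 2k` with natural log and
k = n_subjects + 1. k is constant across methods compared on the same
observations and drops from differences; only differences are
interpreted, with |ΔAIC| > 3 decisive and ties broken by method name.
Paired t, two-sided p and paired Cohen's d (mean/SD of differences)
accompany the AIC. Zero-variance differences leave t undefined (flagged);
the AIC is still computed.

The unbiasedness check permutes condition labels within subject
(preserving per-subject trial counts), re-aggregates trial scores,
recomputes the paired t, and averages t and p over (by default 1 000)
seeded permutations. A hook (`score_fn`) allows re-running a full model
inversion per permutation instead of re-aggregating trial scores.

## Synthetic sessions

The generator emulates the reference acquisition design: 80 CS+ and 80
CS− in random order (configurable), 4-s CS, ITIs drawn uniformly from
{7, 9, 11} s, 3.5-s CS→US delay, and exactly half of the CS+ reinforced
(shuffled half-split, not Bernoulli). Breathing periods are
Normal(4.0, 0.4) s truncated above 1.5 s. Per-cycle amplitude =
base (5.0) + LTI response sampled at the cycle onset + Gaussian noise +
slow drift (a sum of sinusoids band-limited to 0.0005–0.004 Hz, i.e.
entirely below the 0.01 Hz high-pass — a test confirms preprocessing
removes it). The cycle waveform ramps a phase 0→2π within each cycle,
faster over the inspiratory 45% of the period; the cushion dialect emits
A·(1−cos φ)/2 (smooth minima at onsets), the bellows dialect −A·sin(φ)/2
(negative zero crossing exactly at onset). Peak-to-trough excursion per
cycle equals the cycle amplitude by construction. All randomness flows
through one seeded generator; a seed is mandatory.

Two output levels: `simulate_breathing` renders the raw trace (exercises
the full detection chain); `simulate_amplitude_session` emits the
interpolated, filtered amplitude series directly while preserving the
per-breath observation process — this is what Monte-Carlo studies use for
speed.

**Cohort calibration.** For validity studies, each subject's true
response amplitudes are scaled by Normal(1, 0.35) draws (between-subject
variability in conditioning strength). The cohort condition
(`cohort_config`) uses true betas of ∓0.15 (ER negative, LR positive for
CS+; zero for CS−) with per-cycle noise SD 1.2, calibrated once so the
model-based (G3) CS+/CS− discrimination lands at a paired d ≈ 0.6–0.7,
the size observed in fear-conditioning cohorts of this kind. The small
effect keeps cycle amplitudes far from zero, preserving the generator's
linearity. Under these conditions, across seeded replicates of 24-subject
cohorts (40 trials/condition), G3 undercuts every peak-scoring AIC in
~88% of replicates with a mean AIC gap of ≈ 11.

**What the generator does not emulate:** CO₂ dynamics, respiratory sinus
arrhythmia coupling, movement artifacts, device nonlinearities, amplitude
saturation at lung-capacity bounds, or non-stationary learning across the
session. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
every violation real data can present.

## Numerical and procedural choices

- Interpolation grid 10 Hz; trace rendering 50 Hz (ample for ~0.25 Hz
  breathing and cheap enough for Monte-Carlo studies).
- Monte-Carlo problem sizes in the test suite (e.g. 200 replicates of
  24-subject cohorts at 40 trials/condition; 60–120 replicates for
  bias/null-calibration checks) were chosen to keep Monte-Carlo error
  well below the asserted margins at interactive runtimes.
- CS onsets are rounded to the nearest grid sample; events outside the
  data span are errors, trials without 4 s of pre- or 11 s of post-data
  are excluded with a warning.
- Pipeline runs are deterministic given their configuration; every run
  writes a provenance record (config, package version, seed).

## Known limitations

- The canonical RF parameters are shipped, not re-estimated; per-subject
  RF estimation is out of scope.
- Condition-wise estimation precludes trial-by-trial response estimates.
- The onset detector's absolute timing carries device-dependent offsets
  of up to a few hundred milliseconds (filter and median-plateau effects);
  amplitude extraction is insensitive to these, but latency analyses
  should not rely on the detector's absolute timing.
- AIC comparisons are valid only between methods scored on identical
  observations; the implementation enforces this.
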