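# Methods

This note documents the models, estimators, and numerical choices behind
`megspeech`, the assumptions they make, and what the synthetic-data tests
do and do not establish about real recordings.

## Data model

An `EpochSet` is a trial × channel × sample block with a sampling rate,
a time origin at stimulus onset, ordered channel labels, and one metadata
row per trial (participant, cohort ∈ {healthy, patient}, phrase 1–5, trial
index, validity flag). The reference task design is a delayed reading
paradigm: epochs span −0.5 to +4.5 s around stimulus onset, the covert
(imagined-speech) segment is the 1–2 s window and the overt (articulation)
segment the 2–4.5 s window. At full scale a recording has 196 usable
gradiometers at 1 kHz and 60 trials per phrase per participant, 3
participants per cohort; the reduced desk scale used for routine testing
keeps the layout but with 32 channels and 20 trials per phrase.

Containers are HDF5: one group per participant, one dataset per phrase,
with per-trial attributes and a stored global ordering so the round trip
is bit-exact.

## Signal conditioning

Fixed order: low-pass/resample → power-line notch → segment parsing →
channel exclusion / trial screening.

- **Low-pass + resampling.** 4th-order Butterworth at 250 Hz followed by
  polyphase resampling to 1 kHz. The polyphase stage uses its own FIR at
  the output Nyquist; the Butterworth is the anti-alias guard. Applied
  forward–backward (zero-phase), which squares the magnitude response:
  ≈ −33 dB at 400 Hz and ≈ −44 dB at 500 Hz. Zero-phase application is a
  deliberate choice — the cost is a doubled effective order, the benefit
  is no phase distortion of band-power timing.
- **Notch.** 2nd-order IIR notches at 60 Hz and every harmonic below
  Nyquist, each with a fixed 2 Hz −3 dB bandwidth, applied zero-phase:
  > 50 dB at the line frequency, < 0.5 dB at ±5 Hz.
- **Trial screening.** Visual artifact rejection is replaced by a
  deterministic rule: drop trials whose peak |amplitude| exceeds a
  threshold (default 5× the median trial peak), then keep the first 60
  surviving trials per participant × phrase cell. ICA cleanup is exposed
  only as a hook accepting an externally computed keep/drop trial mask;
  the decomposition itself is out of scope.

## Band power

Welch PSD (1 s Hann windows, 50% overlap, constant detrend) integrated
over each band with the trapezoidal rule on the **closed** interval
[lo, hi]. Closed-interval integration makes power additive across bands
that share an edge (1–4 | 4–8 | 8–16 | 16–30 Hz) while the 59–61 Hz gap
keeps the line frequency out of every band. A unit-amplitude in-band
sinusoid yields its analytic power A²/2 within 5%; white-noise band power
is proportional to bandwidth within 10%. The minimum requirement is two
PSD bins inside the band; with the 1 s covert window this gives the delta
band a coarse 4-point estimate, accepted deliberately because the study
design itself fixes that window. Powers are reported in linear units;
log10 is a classifier-side option.

## Sensor correlation and AEC connectivity

Pearson matrices are computed per trial and averaged arithmetically on
*r* (a Fisher-z option exists but is off by default, matching the
plain-average definition of the summaries). Correlation density is the
mean absolute off-diagonal value; strong pairs use a strict |r| > 0.5.
The central 95% range of pooled correlations is a seeded bootstrap of the
sample quantiles — an operational stand-in for an underspecified
Monte-Carlo interval procedure, chosen for reproducibility.

AEC band-passes with the zero-phase 4th-order Butterworth, takes the
Hilbert-envelope magnitude, trims 100 ms per edge, and correlates
envelopes. Two aggregations: per-trial matrices averaged across trials,
or trials concatenated end-to-end after filtering with a single envelope
extraction. No leakage orthogonalization is applied; the measure is plain
sensor-space AEC. The edge trim is load-bearing, not cosmetic: the filter
transients decay toward the trial edges, imprinting a common envelope
profile on every channel that biases untrimmed AEC upward by ≈ +0.05 on
2.5 s trials; trimmed AEC of independent channels is unbiased. Trials
must span at least two periods of the band's lower edge, so delta-band
AEC on the 1 s covert window is rejected; the pipeline's connectivity
stage defaults to the beta band, where the group hypothesis lives.

## Inference

Group comparisons use pooled-variance Student t-tests on
participant × phrase summary statistics (15 per cohort at full scale,
hence df = 28) — never on single trials, which would pseudo-replicate.
The band comparison is a one-way fixed-effects ANOVA over six bands with
the five per-phrase mean distances as samples (df = 5, 24), followed by
Tukey HSD. Distances entering inference are unnormalized; the joint
min-max normalization across bands exists only for presentation.

## Classification

Two-class regularized LDA on standardized per-channel band powers:

- pooled within-class covariance S (divisor n−2);
- shrinkage S_γ = (1−γ)S + γ diag(S), γ ∈ [0, 1];
- weights w = S_γ⁻¹(μ₁−μ₀), bias from class means and empirical priors;
- coefficient threshold: w_j ← 0 where |w_j| ≤ δ; if every weight is
  zeroed the model predicts the prior-majority class.

Features are standardized with training-fold statistics only, which makes
the δ grid comparable across bands (full LDA is affine-equivariant at
γ = 0, but diagonal shrinkage is scale-sensitive). Hyperparameters come
from an exhaustive seeded grid (γ ∈ {0, 0.01, 0.1, 0.3, 0.5, 1},
δ ∈ {0, 10⁻⁴, 10⁻³, 10⁻²}) scored by stratified 10-fold accuracy on the
training data of each outer fold; ties break toward more regularization
(larger γ, then larger δ). A stochastic Bayesian optimizer would not be
reproducible across runs; the grid is deterministic and auditable. Grid
points whose covariance is singular (γ = 0 with more features than
trials) score −∞ and are never selected.

The outer loop is leave-one-participant-pair-out: one fold per
(healthy, patient) pair, trained on all trials of the remaining
participants irrespective of phrase — 9 folds at 3+3 participants, each
with 1,200 training and 600 test trials at full scale. The summary is
the median fold accuracy. A dedicated test verifies the absence of
information leaks: removing the held-out pair's trials from the container
leaves the fold's fitted weights byte-identical.

## Synthetic cohort generator

Per channel c and band b the oscillatory part is

    x_cb = σ_b · ( √(1−ρ²) · p_cb + ρ · s_b )

with p_cb a private and s_b a per-trial shared unit-variance band-limited
source and ρ the cohort coupling. The √(1−ρ²) private weight keeps the
per-band channel variance independent of ρ, so the expected in-band pair
correlation is exactly ρ² while band power is governed solely by σ_b —
the connectivity and power effects can be planted independently. On top:
1/f (pink) noise per channel, a common 60 Hz line sinusoid with random
phase per participant, and an overt-window gain (default 1.3) applied to
the oscillatory sources only — scaling the noise floor too would leave
Pearson r unchanged and could not reproduce a stronger overt correlation.

The patient cohort differs only via a beta amplitude gain g_beta and its
coupling ρ_patient. Presets: `null` (identical cohorts, ρ = 0.3,
g_beta = 1) and `beta-effect` (g_beta = 1.5, ρ_patient = 0.6 vs
ρ_healthy = 0.3). The effect sizes are chosen so the reduced desk scale
recovers all four qualitative directions (higher patient correlation
density, beta as the argmax distance band, higher patient beta AEC, and
best classification from beta features); they are working values for a
detectable effect, not estimates from any real cohort.

Band sources use the magnitude response of the zero-phase 4th-order
Butterworth band-pass applied as a spectral shaping of white noise: the
sum of independent Gaussian band-limited sources is itself Gaussian with
the summed PSD, so one rFFT shaping per channel block generates the whole
private oscillatory background — distributionally identical to filtering
white noise per band but an order of magnitude faster. The elementary
`bandlimited_source` keeps the literal filter implementation and serves
as the cross-check. Generation is float32 and bit-reproducible given the
seed; each (cohort, participant) draws from its own spawned substream.

What the generator does **not** emulate: participant-level random
effects (every participant in a cohort is statistically identical, so
leave-one-pair-out generalization is easier than on real people), head
geometry and sensor forward fields, non-stationarity within trials,
movement or ocular artifacts, and any spatial correlation structure
beyond the single shared source per band. Passing the planted-effect
tests therefore demonstrates that the estimators recover effects of the
assumed form at the stated sizes — not that real cohorts are separable.

## Problem sizes and calibration checks

Routine tests use the reduced scale (32 channels, 3+3 participants,
5 phrases × 20 trials, 5 s epochs at 1 kHz). The acceptance suite checks:
design arithmetic (9 folds of 1,200/600 trials, df = 28, 196 retained
channels) exactly; null calibration over 20 seeded null datasets
(one-sided density tests reject at ≤ 7%, classification within 3 SE of
the 50% chance level over 5 datasets); planted-effect recovery in all
four directions (classification over 10 seeds); and the independent-oracle
equivalences (naive AEC loop at 10⁻⁸, diagonal-LDA closed form, hand
arithmetic for the correlation summaries, F = t² for two groups).
`scripts/acceptance.py` recomputes the null chance-level calibration from
scratch over 10 datasets derived from a single seed.
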