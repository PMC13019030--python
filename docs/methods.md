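# Methods

This note documents the measurement models, the inference layer, the
synthetic data generator, and the numerical choices in `dyadscope`.

## Measurement pipeline

### Gaze

Eye-tracking samples flagged as blinks, plus every sample within
100 ms (`blink_pad_ms`) of a blink sample, are marked invalid; the
masked fraction is reported as `data_loss_pct`. Invalid spans of every
ray component (origins and directions of both eyes) are filled with
shape-preserving piecewise cubic Hermite interpolation (monotone
between knots, so no overshoot across a gap); leading/trailing invalid
spans are held at the nearest valid value. All components are then
low-pass filtered with a second-order Butterworth response at 10 Hz
applied forward–backward. Zero-phase filtering is used because a
one-pass filter's group delay would misalign gaze with the speech
phases it is conditioned on. Filtering operates on Cartesian
components with post-hoc renormalization of the direction vectors —
adequate for the sub-degree smoothing this performs.

A sample is classified *at-eyes* when the minimum, over the left ray,
the right ray, and the cyclopean ray (midpoint origin, normalized mean
direction), of the visual angle to either of the partner's eye centers
is ≤ 2° (inclusive). The OR rule over eyes and rays tolerates minor
oculomotor irregularities such as strabismus. Interpolated samples are
classified and included in summaries (data loss is reported
separately); `include_interpolated_gaze=False` excludes them. Targets
sampled on a different clock are aligned by nearest neighbor within
half a sample period.

At-eyes percentages are summarized separately over the participant's
own *speaking* samples and own *listening* samples; overlap and mutual
silence enter neither denominator.

### Speech

Voicing is amplitude strictly greater than 2 on the 0–100 microphone
scale ("exceeded" is read as strict; amplitude exactly 2 is unvoiced).
Maximal voiced runs separated by ≤ 2 s of silence are fused *before*
duration classification — the ordering matters: a long turn with
hesitation pauses must not be shredded into sub-second fragments and
discarded. Fused segments shorter than 1 s are backchannels ("ok",
"hmm"); they create no speaking/listening phase changes and never
count as interruptions. All intervals are half-open `[start, end)`;
a sample at time `t` covers `[t, t + dt)`.

A turn whose onset lies strictly inside a partner turn is an
interruption attributed to the late starter; exactly simultaneous
onsets are resolved to the lower participant index (the higher index
is deemed the interrupter). Per-sample phases partition session time:
speaking (own turn only), overlap (both in turns), listening (partner
turn only), silence. Floor-transfer gaps are `own start − partner end`
over consecutive turn pairs with a speaker change and non-negative
lag; interruptive (negative-lag) transfers are excluded, and gaps have
no upper cap.

Summary definitions: `speaking_pct` is the participant's share of the
combined dyad turn time (a share-of-floor measure, so a balanced dyad
sits at 50%); `interrupting_pct` is overlap time initiated by the
participant's own turns divided by session time; `loudness` is the
mean amplitude over the participant's voiced samples inside turns
(backchannels excluded).

### Smiling

The per-sample smile score is the mean of the left and right
mouth-corner action-unit activations (0–100), and the summary is the
mean over *all* frames of the conversation period — no event
detection.

### Cardiac

R peaks are detected with the two-event-related-moving-averages
method: third-order Butterworth band-pass 8–20 Hz (zero-phase),
squaring, then a QRS-scale moving average (120 ms) compared against a
beat-scale moving average (600 ms) plus an offset of 0.08 × the mean
squared signal; blocks where the QRS average exceeds the threshold and
that are at least one QRS window wide each contribute the time of the
squared-signal maximum. Window lengths and the offset fraction are the
method's published defaults and are module constants.

RR artifact repair replaces manual visual inspection with an explicit
rule: intervals outside [300, 2000] ms or deviating > 30% from the
previous accepted interval are replaced by linear interpolation
between accepted neighbors; the correction count is reported and a
series with > 20% corrections is flagged low-quality.

Heart rate is `60 / mean(RR in s)`. For HF-HRV the RR series (ms,
attributed to each interval's closing beat) is interpolated with a
cubic spline onto a fine uniform grid (32 Hz) and Fourier (bandlimited)
resampled to 4 Hz, mean-detrended, and Welch-transformed with 30 s
Hann windows at 50% overlap. The one-sided density is normalized so
that its integral over frequency equals the series variance (Parseval,
verified to ±5% in tests); HF power is the trapezoidal integral of the
density over 0.15–0.4 Hz with interpolated band edges, in ms², and
HF-HRV is its natural log. Units follow from physiology: typical HF
powers of a few hundred ms² give log values near 6, the expected
range. Whether HF-HRV should be computed per conversation topic or per
session is a design choice; the default is per session
(`cardiac_scope="session"`, the value repeated across topic rows),
with per-topic computation available.

## Trait factors

Each trait construct is the first principal component of its
questionnaire scales: 4 social-anxiety scales, 8 general-psychopathology
scales, 5 verticality scales. PCA runs on the correlation matrix
(scales z-scored first) because the scales have wildly different
ranges. Scores are standardized and the component sign is anchored so
that social interaction anxiety, trait anxiety, and personal sense of
power load positively on their respective factors — making "higher =
more anxious / more psychopathology / more verticality" reproducible.
Scales keyed against their factor (favorable social comparison,
empathizing, extraversion, self-esteem) then load negatively, which
`validate_loadings` reports. Missing scale values are handled
complete-case per group with a logged count. Cronbach's alpha is
provided as a utility for item-level data.

## Association models

All nine measures are pooled over participants and topics, winsorized
at ±3 SD (bounds from the pre-winsorization moments), and z-scored
with the post-winsorization moments; the corrected percentage is
logged per measure. Winsorization is pooled rather than per topic —
the per-topic alternative would move the clip bounds with topic means.

Each trait × measure association is a linear mixed model
`measure ~ trait` with a random intercept per participant, fitted by
REML (statsmodels `MixedLM`, default optimizer and convergence
settings). The design calls for a topic-within-participant random
component; with exactly one observation per participant × topic cell
such a component contributes σ²·I inside each participant block and is
therefore exactly confounded with the residual — the marginal
covariance, and with it β, SE, t, and p, is identical to the
random-intercept model, while the over-parameterized fit sits on a
likelihood ridge and fails sporadically. The identifiable equivalent
is therefore the default; `include_topic_vc=True` requests the literal
parameterization (it agrees to ~3 decimals in tests) with automatic
fallback on non-convergence.

Reported per test: standardized β, Wald 95% CI (β ± 1.96·SE),
t = β/SE, df fixed at `N_participants − 2` (128 participants give
t on 126 df; the ECG subsample of 121 gives 119), and a two-sided p
from the t distribution. The df convention is configurable
(`df_convention="n_obs"` uses observation-level df). p values are
BH-FDR adjusted over the family of all trait × measure tests in a run
(27 at the full design); the family size is recorded with the results.

Cross-trait pattern similarity is the Pearson correlation between two
traits' β vectors over the nine measures, with
`t = r·sqrt(n−2)/sqrt(1−r²)` on `df = n − 2 = 7` and a Fisher-z 95%
interval. Statistical power for a correlation uses the Fisher-z
approximation with the `ρ/(2(n−1))` bias correction, cross-checked by
Monte Carlo over bivariate normal samples; both values are returned.

## Synthetic dyad generator

The generator defines the study conditions under which everything is
tested: 64 dyads (128 participants) by default, three 10-minute topics
per session, 50 Hz gaze/audio/face streams (headset rates are not
dictated by the emulated design; these are configurable defaults), ECG
as R-peak times (`rr_only`) or a rendered 1000 Hz trace, and 7 of 128
participants missing cardiac data.

**Traits.** Latents (SA, P, V) are a correlated trivariate normal;
the default intercorrelations (SA–P 0.6, SA–V and P–V −0.4) reflect
the strong overlap of social anxiety with general psychopathology and
their opposition to verticality. Each of the 17 scale scores is
`sign × 0.7 × (group latent) + noise`, affinely mapped to its
population mean/SD and clipped to its admissible range.

**Measure targets.** For measure *m*, the per-participant, per-topic
target in standardized units is `Σ_t effect[t,m]·latent_t + a·u + b·e`
with a stable participant deviation `u` and per-topic deviation `e`
splitting the residual variance 50/50 and topping the total up to 1 —
so a standardized regression on a latent trait recovers the configured
effect entry. Effect entries are *generative* (partial) coefficients;
with correlated traits the marginal associations differ accordingly.
Targets are Gaussian and unbounded; physical clipping (e.g. loudness
≥ 2.05 so speech stays voiced, gaze percentages inside (2, 98)) is
applied only when streams are rendered. Population baselines (means
and SDs: 23.05/11.96% gaze while speaking, 49.45/16.96% while
listening, 13.40/7.99 smiling, 50.73/9.90% speaking share, 4.82/3.79%
interrupting, 1.36/0.70 s gaps, 2.70/0.77 loudness, 79.61/11.95 bpm,
6.36/0.96 log-ms² HF-HRV) are the descriptive statistics of the
student sample the generator emulates.

**Conversation.** A semi-Markov alternation: exponential turn
durations (minimum 1.5 s so every turn survives the 1 s rule),
gamma-distributed floor-transfer gaps (shape 3.8, from the gap
mean/SD ratio), Poisson backchannels of 0.2–0.8 s inside partner
turns, and interruptive onsets that advance the next turn before the
current offset with a per-participant probability derived from the
interrupting-time target. Two scheduling guards keep the generator's
ground truth exactly recoverable by the segmentation rules: events of
the same speaker stay > 2 s apart (so fusion reconstructs exactly the
scheduled segments, including across topic boundaries), and overlaps
are at least 0.25 s (so they cannot quantize away at the stream rate
and flip a transfer's classification). Speaking-share targets set the
relative mean turn durations within the dyad; because the realized
share is a within-dyad compromise, share and interruption measures
carry genuine dyadic constraint noise.

**Gaze.** A two-state (at-eyes/away) Markov chain with ~2 s mean
dwell and phase-dependent stationary probabilities equal to the gaze
targets, rendered geometrically: rays from the participant's eye
origins toward a partner eye center, rotated off-target by ~0.1–1.2°
during at-eyes visits and 6–12° during away visits (the away floor of
6° keeps an off-ray from accidentally falling within 2° of the *other*
eye, which sits ~3.7° away at 1 m). Offset magnitude, azimuth, and the
aimed eye all vary smoothly (cosine ramps of 120 ms, slow continuous
azimuth rotation), so the rendered direction has no discontinuities —
this is what makes the preprocessing chain transparent on clean data
(< 0.5 percentage-point summary change with filtering on vs off, a
tested invariant). Blinks are Poisson (0.11 Hz, 150 ms closure, chosen
to reproduce ~3.9% data loss after the ±100 ms guard) and corrupt the
rays while the lids are closed, which exercises masking and
interpolation. Partner head sway makes the eye-center targets
time-varying.

**Smiling.** A baseline-plus-events action-unit trace rescaled so the
per-topic mean equals the (non-negative) target, with an additive
correction loop compensating clipping at 100; a slow left/right
asymmetry exercises the two-channel mean.

**Cardiac.** RR(t) = mean RR (from the heart-rate target) + A·sin(2π·
0.3 Hz·t) + white noise (8 ms), with A = sqrt(2·exp(HF target)) so the
sinusoid's power A²/2 realizes the HF-HRV target; beats iterate
`t += RR(t)`. Cardiac targets drift linearly between topic midpoints —
heart rate does not step discontinuously at topic boundaries, which
would otherwise trigger spurious artifact cascades in the 30% RR rule.
In `full_ecg` mode a PQRST template train is rendered at 1000 Hz with
white noise at a configurable SNR to exercise the detector.

**What the generator does not emulate.** Real speech acoustics (only
amplitude envelopes), eye-tracker calibration drift and saccade
kinematics, ectopic beats and real ECG artifact morphology, topic
content effects, and any dyadic feedback between channels (gaze does
not react to the partner's smiles, for example). Passing tests
therefore demonstrate that the measurement chain is correct and the
inference calibrated under the stated generative assumptions — not
that the pipeline is robust to every pathology of field recordings.

## Problem sizes used in tests

The test suite runs the full design size (128 participants, 3 topics)
wherever only the statistical stage is involved: 1000 replicates for
type-I error calibration, 200 for effect recovery and CI coverage,
50 runs for cross-trait sign-pattern recovery. Stream rendering is
exercised on smaller sessions (up to 8 dyads, 40–300 s topics), which
is ample for the extraction-accuracy checks because extraction error
is governed by samples per topic, not by the number of dyads. The
turn-taking oracle sweep uses 1000 random 20 s dyads at 25 Hz against
a brute-force per-sample state machine.

## Known limitations

- The FDR family is all trait × measure tests of one run (27); other
  family choices change adjusted significance.
- The df = N − 2 convention is a fixed approximation, not a
  Satterthwaite computation; for balanced designs with ≥ 100
  participants the difference is negligible.
- HF-HRV of very short windows (< 60 s) is undefined by construction
  and reported missing.
- Winsorization percentages, RR correction counts, and data loss are
  reported but no automatic exclusion of low-quality participants is
  performed beyond flagging.
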