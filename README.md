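# dyadscope

Behavioral and physiological phenotyping of dyadic social-VR
interactions, with a trait-association inference layer and a seeded
synthetic dyad generator that makes the whole pipeline testable end to
end.

## The problem

When two people converse through avatars in social VR, the platform
records rich interaction streams for free: binocular eye-gaze rays and
blinks, the partner's eye positions, the microphone amplitude
envelope, facial action-unit activations, and (with a chest sensor) an
ECG. Clinically relevant traits — social anxiety, general
psychopathology (the *p*-factor), and verticality (dominance/rank) —
are expected to leave measurable fingerprints in these streams:
socially anxious speakers look less at their partner's eyes while
speaking, talk more quietly, leave longer gaps before responding, and
show reduced high-frequency heart-rate variability (HF-HRV).

`dyadscope` implements the full measurement and inference chain for
this kind of study:

1. **Gaze** — blink masking (±100 ms guard), piecewise cubic Hermite
   interpolation, zero-phase 2nd-order Butterworth smoothing (10 Hz),
   and at-eyes classification: a sample counts as directed at the
   partner's eye region if the left, right, or combined (cyclopean)
   gaze ray passes within 2° of visual angle of either eye center.
   At-eyes fractions are reported separately for speaking and
   listening phases.
2. **Speech** — voicing at amplitude > 2 (0–100 scale), fusion of
   runs separated by pauses ≤ 2 s, segments < 1 s classified as
   backchannels, interruption attribution to the participant who began
   speaking while previously listening, floor-transfer gaps, share of
   speaking time, and loudness.
3. **Smiling** — mean of the left/right mouth-corner action units,
   averaged over the conversation.
4. **Cardiac** — R-peak detection with the two-event-related
   moving-averages method (8–20 Hz band-pass, squaring, 120 ms vs
   600 ms moving averages), automated RR artifact repair, heart rate
   `60 / mean(RR)`, and HF-HRV: RR resampled at 4 Hz (cubic spline +
   bandlimited resampling), Welch PSD (30 s Hann windows, 50% overlap),
   and the natural log of the 0.15–0.4 Hz band power in ms².
5. **Trait factors** — first principal components of the grouped
   questionnaire scales (4 social-anxiety, 8 psychopathology, 5
   verticality scales), sign-anchored and standardized.
6. **Inference** — per measure: 3-SD winsorization and
   z-standardization, then linear mixed models
   `measure ~ trait + (1 | participant)` over participant × topic
   observations, with standardized β, Wald 95% CI (β ± 1.96·SE),
   t = β/SE on df = N − 2, Benjamini–Hochberg FDR over the 27
   trait × measure tests, and cross-trait similarity as the Pearson
   correlation between two traits' β vectors over the nine measures.

The synthetic generator (`dyadscope.synthetic_dyads`) draws correlated
latent traits, maps them to 17 questionnaire scale scores, and renders
raw streams whose extracted measures carry configurable standardized
trait effects — so parameter recovery, type-I error calibration, and
the full extraction chain can be verified without any participant
data.

## Worked example

```bash
dyadscope simulate --out study --seed 3 --n-dyads 8 --topic-duration 120
dyadscope extract study --out summary.csv
dyadscope model summary.csv study/traits.csv --out results
```

The `model` step prints the report below (this run simulates 8 dyads
with no injected trait effects, so every cell is a null draw):

```
Trait-behavior associations (standardized beta [95% CI])

measure                                   sa                         p                         v
gaze_speaking           -0.19 [-0.59,+0.20]       -0.48 [-0.81,-0.16].      +0.05 [-0.35,+0.46]
gaze_listening          -0.03 [-0.43,+0.37]       -0.18 [-0.57,+0.21]       +0.12 [-0.27,+0.51]
smiling                 -0.40 [-0.78,-0.02]       -0.42 [-0.80,-0.05].      -0.18 [-0.60,+0.25]
speaking_pct            +0.38 [+0.01,+0.74]       +0.23 [-0.16,+0.63]       -0.03 [-0.44,+0.38]
interrupting_pct        +0.06 [-0.25,+0.37]       -0.05 [-0.36,+0.27]       +0.01 [-0.31,+0.32]
mean_gap_s              +0.11 [-0.24,+0.47]       +0.10 [-0.26,+0.46]       -0.14 [-0.50,+0.21]
loudness                -0.06 [-0.48,+0.36]       +0.16 [-0.25,+0.57]       -0.00 [-0.42,+0.42]
heart_rate_bpm          -0.28 [-0.56,+0.01]       +0.12 [-0.17,+0.42]       +0.07 [-0.23,+0.37]
hf_hrv                  +0.34 [+0.06,+0.62].      +0.36 [+0.08,+0.64].      -0.37 [-0.65,-0.09].

('.' p<= 0.05 uncorrected, '*' FDR-significant; family = 27 tests)

Cross-trait behavior-pattern similarity (Pearson r over betas)
  sa vs p: r=+0.72 [+0.11,+0.94], t(7)=+2.76, p=0.028 (over 9 measures)
  sa vs v: r=-0.38 [-0.83,+0.38], t(7)=-1.07, p=0.319 (over 9 measures)
  p vs v: r=-0.35 [-0.82,+0.41], t(7)=-1.00, p=0.35 (over 9 measures)

factor sa: first component explains 77.8% of its 4 scales
factor p: first component explains 62.2% of its 8 scales
factor v: first component explains 53.7% of its 5 scales
```

Each cell is the standardized mixed-model effect of one trait factor
on one behavioral measure with its 95% interval (`.` marks p ≤ .05
uncorrected, `*` FDR-significant). The similarity lines quantify how
parallel (or inverted) two traits' behavioral signatures are. With
only 16 participants, as here, intervals are wide and a few null cells
cross p < .05 by chance (none survive the FDR); at the design size
(64 dyads = 128 participants) the pipeline recovers effects of ±0.2
with a standard error of about 0.07. To inject effects, pass an
`effect_matrix` to `SyntheticConfig` (e.g.
`synthetic_dyads.reported_effect_matrix()` or
`synthetic_dyads.hypothesis_sign_matrix(0.2)`) via the library API.

The same stages are available as library calls: `run_simulate`,
`run_extract`, `run_model` in `dyadscope.session_runner`.

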