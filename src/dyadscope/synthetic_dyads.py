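"""Seeded synthetic dyadic social-VR interaction sessions.

This module emulates the raw data streams produced by a two-person
avatar-mediated VR conversation — binocular eye-gaze rays with blinks,
the partner's eye-center positions, a microphone amplitude envelope,
mouth-corner action-unit traces, and an interbeat (RR) series or raw
ECG — together with a questionnaire table of 17 trait scale scores.

The generator is organized in two stages:

1. A statistical stage (:func:`sample_traits`,
   :func:`sample_behavior_targets`) draws correlated latent traits
   (social anxiety, general psychopathology, verticality) and, from a
   configurable trait-by-measure effect matrix, per-participant,
   per-topic *target* values for the nine behavioral/physiological
   measures. Targets are Gaussian on each measure's natural scale,
   with total unit variance in standardized units so that a
   standardized regression of a measure on a latent trait recovers the
   configured effect-matrix entry.
2. A rendering stage (:func:`generate_session`, :func:`generate_study`)
   realizes those targets as raw streams: a semi-Markov alternating
   turn process with gamma-distributed floor-transfer gaps, Poisson
   backchannels and occasional overlapped (interruptive) onsets; a
   two-state at-eyes/away gaze process rendered geometrically as 3-D
   rays that do or do not pass within the at-eyes cone of the
   partner's eye centers; a smile action-unit trace; and an RR series
   with a sinusoidal 0.3 Hz respiratory component whose amplitude sets
   high-frequency heart-rate variability.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "TRAIT_NAMES",
    "MEASURE_BASELINES",
    "SCALE_TABLE",
    "SCALE_GROUPS",
    "ANCHOR_SCALES",
    "SyntheticConfig",
    "TraitProfile",
    "sample_traits",
    "sample_behavior_targets",
    "generate_session",
    "generate_study",
    "synthesize_ecg",
    "reported_effect_matrix",
    "hypothesis_sign_matrix",
    "default_trait_correlations",
]

#: Canonical order of the nine behavioral/physiological measures.
MEASURES = (
    "gaze_speaking",
    "gaze_listening",
    "smiling",
    "speaking_pct",
    "interrupting_pct",
    "mean_gap_s",
    "loudness",
    "heart_rate_bpm",
    "hf_hrv",
)

#: Canonical order of the three latent trait factors.
TRAIT_NAMES = ("sa", "p", "v")

#: Population mean and SD of each measure, on its natural scale
#: (percent for gaze/speaking/interrupting, 0-100 AU units for smiling,
#: seconds for gaps, 0-100 amplitude units for loudness, bpm, and
#: natural-log ms^2 for HF-HRV). These are the descriptive statistics
#: of the student sample the generator emulates.
MEASURE_BASELINES = {
    "gaze_speaking": (23.05, 11.96),
    "gaze_listening": (49.45, 16.96),
    "smiling": (13.40, 7.99),
    "speaking_pct": (50.73, 9.90),
    "interrupting_pct": (4.82, 3.79),
    "mean_gap_s": (1.36, 0.70),
    "loudness": (2.70, 0.77),
    "heart_rate_bpm": (79.61, 11.95),
    "hf_hrv": (6.36, 0.96),
}


@dataclass(frozen=True)
class ScaleSpec:
    """One questionnaire scale: population moments, admissible range,
    trait group, and the sign of its loading on the group factor."""

    name: str
    group: str  # "sa" | "p" | "v"
    mean: float
    sd: float
    minimum: float
    maximum: float
    sign: int  # +1 / -1 direction w.r.t. the latent trait


#: The 17 self-report scales, grouped into social anxiety (sa),
#: general psychopathology (p), and verticality (v). Negative signs
#: mark scales keyed opposite to their factor (favorable social
#: comparison, empathizing, extraversion, and self-esteem decrease
#: with their factor).
SCALE_TABLE = (
    ScaleSpec("social_interaction_anxiety", "sa", 25.20, 11.58, 0, 80, +1),
    ScaleSpec("fear_negative_evaluation", "sa", 35.45, 10.16, 12, 60, +1),
    ScaleSpec("fear_positive_evaluation", "sa", 22.69, 12.21, 0, 90, +1),
    ScaleSpec("social_comparison", "sa", 65.79, 11.45, 40, 100, -1),
    ScaleSpec("trait_anxiety", "p", 20.32, 4.36, 10, 40, +1),
    ScaleSpec("stress", "p", 27.24, 4.99, 10, 50, +1),
    ScaleSpec("depression", "p", 2.20, 2.32, 0, 21, +1),
    ScaleSpec("impulsivity", "p", 2.19, 0.38, 1, 4, +1),
    ScaleSpec("empathizing", "p", 12.21, 3.13, 0, 20, -1),
    ScaleSpec("neuroticism", "p", 3.20, 0.81, 1, 5, +1),
    ScaleSpec("extraversion", "p", 3.50, 0.84, 1, 5, -1),
    ScaleSpec("self_esteem", "p", 4.67, 0.77, 1, 6, -1),
    ScaleSpec("social_status", "v", 5.88, 1.22, 1, 10, +1),
    ScaleSpec("power", "v", 29.52, 4.27, 6, 42, +1),
    ScaleSpec("dominance", "v", 2.59, 0.87, 1, 7, +1),
    ScaleSpec("prestige", "v", 4.91, 0.65, 1, 7, +1),
    ScaleSpec("agency", "v", -0.79, 0.50, -2.90, 2.90, +1),
)

SCALE_GROUPS = {
    g: tuple(s.name for s in SCALE_TABLE if s.group == g) for g in TRAIT_NAMES
}

#: Scale used to orient the sign of each trait factor.
ANCHOR_SCALES = {"sa": "social_interaction_anxiety", "p": "trait_anxiety", "v": "power"}


def default_trait_correlations() -> np.ndarray:
    """Latent trait intercorrelations: social anxiety and general
    psychopathology share substantial variance; verticality opposes
    both (moderately)."""
    return np.array([[1.0, 0.6, -0.4], [0.6, 1.0, -0.4], [-0.4, -0.4, 1.0]])


def reported_effect_matrix() -> np.ndarray:
    """Trait-by-measure standardized effects observed in the dyadic VR
    study sample (coefficients reported in the running text; pairs the
    study did not report individually are zero here)."""
    eff = np.zeros((3, 9))
    m = {name: j for j, name in enumerate(MEASURES)}
    # social anxiety
    eff[0, m["gaze_speaking"]] = -0.20
    eff[0, m["smiling"]] = 0.13
    eff[0, m["loudness"]] = -0.18
    eff[0, m["mean_gap_s"]] = 0.11
    eff[0, m["hf_hrv"]] = -0.23
    # general psychopathology
    eff[1, m["gaze_speaking"]] = -0.15
    eff[1, m["gaze_listening"]] = -0.14
    eff[1, m["smiling"]] = 0.14
    eff[1, m["hf_hrv"]] = -0.24
    # verticality
    eff[2, m["smiling"]] = -0.14
    eff[2, m["mean_gap_s"]] = -0.16
    eff[2, m["interrupting_pct"]] = 0.12
    eff[2, m["heart_rate_bpm"]] = -0.16
    eff[2, m["hf_hrv"]] = 0.17
    return eff


def hypothesis_sign_matrix(magnitude: float = 0.2) -> np.ndarray:
    """Effect matrix realizing the hypothesized direction of every
    trait-measure association: social anxiety and psychopathology act
    in the same direction on each measure, verticality in the
    opposite direction.

    Signs per measure (for social anxiety): less gaze at the
    partner's eyes while speaking and listening, more smiling, less
    speaking time, less interrupting, longer gaps, quieter speech,
    higher heart rate, lower HF-HRV.
    """
    sa_signs = np.array([-1, -1, +1, -1, -1, +1, -1, +1, -1], dtype=float)
    return magnitude * np.vstack([sa_signs, sa_signs, -sa_signs])


def _zeros_effects() -> np.ndarray:
    return np.zeros((3, 9))


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study.

    Defaults reproduce the emulated study's conditions: 64 dyads (128
    participants), three 10-minute conversation topics per session,
    and an ECG subsample with 7 participants missing cardiac data.
    Stream sampling rates are not dictated by the emulated study and
    default to 50 Hz for gaze, audio envelope, and face tracking.
    """

    n_dyads: int = 64
    topics_per_session: int = 3
    topic_duration_s: float = 600.0
    sample_rate_gaze_hz: float = 50.0
    sample_rate_audio_hz: float = 50.0
    sample_rate_face_hz: float = 50.0
    ecg_mode: str = "rr_only"  # "rr_only" | "full_ecg"
    ecg_sample_rate_hz: float = 1000.0
    ecg_snr_db: float = 20.0
    trait_correlations: np.ndarray = field(default_factory=default_trait_correlations)
    effect_matrix: np.ndarray = field(default_factory=_zeros_effects)
    missing_ecg_fraction: float = 7.0 / 128.0
    seed: int = 0

    # trait -> scale measurement model
    scale_loading: float = 0.7

    # split of the non-trait measure variance into a stable
    # participant component vs. per-topic fluctuation
    participant_residual_share: float = 0.5

    # conversation process
    mean_turn_s: float = 6.0
    min_turn_s: float = 1.5
    gap_shape: float = 3.8  # gamma shape; (1.36/0.70)^2 from the gap moments
    gap_floor_s: float = 0.35
    overlap_mean_s: float = 1.2
    backchannel_rate_hz: float = 0.05
    backchannel_duration_s: tuple[float, float] = (0.2, 0.8)

    # gaze process
    gaze_dwell_s: float = 2.0
    blink_rate_hz: float = 0.11
    blink_duration_s: float = 0.15
    at_eyes_max_offset_deg: float = 1.2
    away_offset_deg: tuple[float, float] = (6.0, 12.0)
    transition_s: float = 0.12

    # cardiac process
    rr_noise_ms: float = 8.0
    resp_freq_hz: float = 0.30

    def __post_init__(self) -> None:
        self.trait_correlations = np.asarray(self.trait_correlations, dtype=float)
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        R = self.trait_correlations
        if R.shape != (3, 3):
            raise ValueError("trait_correlations must be 3x3")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("trait_correlations must be symmetric")
        if np.min(np.linalg.eigvalsh(R)) <= 1e-10:
            raise ValueError("trait_correlations must be positive-definite")
        if self.effect_matrix.shape != (3, len(MEASURES)):
            raise ValueError(
                f"effect_matrix must be 3x{len(MEASURES)} "
                "(traits sa/p/v by measures)"
            )
        for attr in ("sample_rate_gaze_hz", "sample_rate_audio_hz",
                     "sample_rate_face_hz", "ecg_sample_rate_hz"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.topic_duration_s <= 0:
            raise ValueError("topic_duration_s must be > 0")
        if self.topics_per_session < 1:
            raise ValueError("topics_per_session must be >= 1")
        if not 0 <= self.missing_ecg_fraction < 1:
            raise ValueError("missing_ecg_fraction must be in [0, 1)")
        if self.ecg_mode not in ("rr_only", "full_ecg"):
            raise ValueError("ecg_mode must be 'rr_only' or 'full_ecg'")
        if not 0 <= self.participant_residual_share <= 1:
            raise ValueError("participant_residual_share must be in [0, 1]")


@dataclass
class TraitProfile:
    """Latent standardized traits and questionnaire scale scores of one
    participant."""

    participant_id: str
    latent_sa: float
    latent_p: float
    latent_v: float
    scale_scores: dict[str, float]

    @property
    def latents(self) -> np.ndarray:
        return np.array([self.latent_sa, self.latent_p, self.latent_v])


def sample_traits(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[TraitProfile]:
    """Draw trait profiles for all ``2 * n_dyads`` participants.

    Latent traits are a correlated trivariate normal; each scale score
    is ``sign * loading * (group latent) + sqrt(1 - loading^2) * noise``,
    affinely mapped onto the scale's population mean/SD and clipped to
    its admissible range.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = 2 * config.n_dyads
    chol = np.linalg.cholesky(config.trait_correlations)
    latents = rng.standard_normal((n, 3)) @ chol.T
    lam = config.scale_loading
    noise_sd = math.sqrt(max(0.0, 1.0 - lam * lam))
    group_idx = {g: i for i, g in enumerate(TRAIT_NAMES)}
    profiles = []
    for i in range(n):
        scores: dict[str, float] = {}
        for spec in SCALE_TABLE:
            z = (
                spec.sign * lam * latents[i, group_idx[spec.group]]
                + noise_sd * rng.standard_normal()
            )
            raw = spec.mean + spec.sd * z
            scores[spec.name] = float(np.clip(raw, spec.minimum, spec.maximum))
        profiles.append(
            TraitProfile(
                participant_id=f"p{i:03d}",
                latent_sa=float(latents[i, 0]),
                latent_p=float(latents[i, 1]),
                latent_v=float(latents[i, 2]),
                scale_scores=scores,
            )
        )
    return profiles


def sample_behavior_targets(
    profiles: Sequence[TraitProfile],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-participant, per-topic target values of the nine measures.

    For measure *m* with baseline mean ``mu_m`` and SD ``s_m`` the
    target in standardized units is ``eta + a*u + b*e`` where
    ``eta = sum_t effect_matrix[t, m] * latent_t``, ``u`` is a stable
    participant deviation, ``e`` an independent per-topic deviation,
    and ``a^2 + b^2`` tops the total variance up to 1. The returned
    values are ``mu_m + s_m * (that z-score)`` — Gaussian and
    unbounded; physical clipping happens only when streams are
    rendered. Cardiac columns are NaN for participants in the
    missing-ECG subsample.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(profiles)
    k = config.topics_per_session
    eff = config.effect_matrix
    R = config.trait_correlations
    latents = np.vstack([p.latents for p in profiles])  # n x 3
    eta = latents @ eff  # n x 9

    n_missing = int(round(config.missing_ecg_fraction * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False) if n_missing else []
    missing = np.zeros(n, dtype=bool)
    missing[list(missing_idx)] = True

    rows = []
    for j, meas in enumerate(MEASURES):
        mu, sd = MEASURE_BASELINES[meas]
        explained = float(eff[:, j] @ R @ eff[:, j])
        resid = max(0.05, 1.0 - explained)
        a = math.sqrt(resid * config.participant_residual_share)
        b = math.sqrt(resid * (1.0 - config.participant_residual_share))
        u = rng.standard_normal(n)
        e = rng.standard_normal((n, k))
        z = eta[:, j][:, None] + a * u[:, None] + b * e
        rows.append(mu + sd * z)
    values = np.stack(rows, axis=-1)  # n x k x 9

    records = []
    for i, prof in enumerate(profiles):
        for t in range(k):
            rec = {"participant": prof.participant_id, "topic": t}
            for j, meas in enumerate(MEASURES):
                v = values[i, t, j]
                if missing[i] and meas in ("heart_rate_bpm", "hf_hrv"):
                    v = np.nan
                rec[meas] = v
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.attrs["missing_ecg"] = [profiles[i].participant_id for i in range(n) if missing[i]]
    return df


# ---------------------------------------------------------------------------
# conversation scheduling
# ---------------------------------------------------------------------------


@dataclass
class _Turn:
    speaker: int  # 0 or 1 within the dyad
    start: float
    end: float
    interruption: bool


def _schedule_topic(
    rng: np.random.Generator,
    duration: float,
    mean_turn: tuple[float, float],
    gap_mean: tuple[float, float],
    p_interrupt: tuple[float, float],
    config: SyntheticConfig,
) -> tuple[list[_Turn], list[tuple[int, float, float]]]:
    """Semi-Markov alternating turn schedule for one topic.

    Returns turn intervals (topic-relative, half-open seconds) and
    backchannel intervals ``(speaker, start, end)``. Same-speaker
    events are kept > 2 s apart so that the downstream pause-fusion
    rule reconstructs exactly this schedule.
    """
    turns: list[_Turn] = []
    last_end = [-10.0, -10.0]  # last own-voice end per speaker
    speaker = int(rng.integers(2))
    min_sep = 2.05  # > the 2 s fusion limit
    # first onset beyond the fusion horizon so no run ever fuses with
    # the previous topic's speech
    t = float(rng.uniform(min_sep + 0.05, 4.0))
    while t < duration:
        dur = config.min_turn_s + rng.exponential(
            max(0.1, mean_turn[speaker] - config.min_turn_s)
        )
        end = min(t + dur, duration)
        if end - t >= config.min_turn_s:
            turns.append(_Turn(speaker, t, end, False))
            last_end[speaker] = end
        nxt = 1 - speaker
        interrupt = (
            rng.random() < p_interrupt[nxt]
            and end < duration
            and end - t >= config.min_turn_s
        )
        if interrupt:
            lead = min(
                max(rng.exponential(config.overlap_mean_s), 0.3),
                0.8 * (end - t),
            )
            onset = max(end - lead, t + 0.2, last_end[nxt] + min_sep)
            # overlaps below the stream resolution would quantize away
            # and flip the transfer's classification downstream
            if onset > end - 0.25:
                onset = end + max(config.gap_floor_s, 0.1)
        else:
            g = config.gap_floor_s + rng.gamma(
                config.gap_shape,
                max(0.05, (gap_mean[nxt] - config.gap_floor_s)) / config.gap_shape,
            )
            onset = end + g
        onset = max(onset, last_end[nxt] + min_sep)
        if onset >= duration:
            break
        # mark whether the next turn starts inside the current one
        t_prev_end = end
        t = onset
        speaker = nxt
        if t < t_prev_end:
            # flagged when the turn is appended on the next loop pass
            pass
    # rebuild interruption flags from realized overlaps
    for i, tu in enumerate(turns):
        other = [o for o in turns if o.speaker != tu.speaker]
        tu.interruption = any(o.start < tu.start < o.end for o in other)

    # backchannels: short vocalizations while the partner holds the floor,
    # kept clear of the speaker's own turns so no fusion can occur
    backchannels: list[tuple[int, float, float]] = []
    for sp in (0, 1):
        own = [tu for tu in turns if tu.speaker == sp]
        partner = [tu for tu in turns if tu.speaker != sp]
        for tu in partner:
            span = tu.end - tu.start
            n_bc = rng.poisson(config.backchannel_rate_hz * span)
            for _ in range(n_bc):
                d = rng.uniform(*config.backchannel_duration_s)
                s = rng.uniform(tu.start, tu.end - d) if tu.end - tu.start > d else None
                if s is None:
                    continue
                e = s + d
                clear = all(
                    e <= o.start - min_sep or s >= o.end + min_sep for o in own
                ) and all(
                    e <= b_e0 - min_sep or s >= b_e1 + min_sep
                    for b_sp, b_e0, b_e1 in backchannels
                    if b_sp == sp
                )
                if clear:
                    backchannels.append((sp, s, e))
    backchannels.sort(key=lambda b: b[1])
    return turns, backchannels


def _speech_truth(
    turns: list[_Turn], duration: float
) -> list[dict[str, float]]:
    """Analytic speech summaries implied by a realized schedule, using
    the same definitions the extraction pipeline applies."""
    out = []
    for sp in (0, 1):
        own = sorted([t for t in turns if t.speaker == sp], key=lambda t: t.start)
        other = sorted([t for t in turns if t.speaker != sp], key=lambda t: t.start)
        own_time = sum(t.end - t.start for t in own)
        other_time = sum(t.end - t.start for t in other)
        # overlap attributed to the later-starting (interrupting) turn
        intr_time = 0.0
        for t in own:
            if not t.interruption:
                continue
            for o in other:
                lo, hi = max(t.start, o.start), min(t.end, o.end)
                if hi > lo and o.start <= t.start:
                    intr_time += hi - lo
        # floor-transfer gaps
        ordered = sorted(turns, key=lambda t: t.start)
        gaps = [
            cur.start - prev.end
            for prev, cur in zip(ordered, ordered[1:])
            if cur.speaker == sp and prev.speaker != sp and cur.start >= prev.end
        ]
        out.append(
            {
                "speaking_pct": 100.0 * own_time / (own_time + other_time)
                if own_time + other_time > 0
                else np.nan,
                "interrupting_pct": 100.0 * intr_time / duration,
                "mean_gap_s": float(np.mean(gaps)) if gaps else np.nan,
                "n_turns": float(len(own)),
            }
        )
    return out


# ---------------------------------------------------------------------------
# stream rendering
# ---------------------------------------------------------------------------


def _render_amplitude(
    t: np.ndarray,
    turns: list[_Turn],
    backchannels: list[tuple[int, float, float]],
    speaker: int,
    loudness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude envelope on the 0-100 scale: the participant's
    per-topic loudness level while voicing, low noise otherwise."""
    amp = np.abs(rng.normal(0.0, 0.3, t.size))
    amp = np.minimum(amp, 1.5)
    level = max(2.05, loudness)
    for tu in turns:
        if tu.speaker == speaker:
            amp[(t >= tu.start) & (t < tu.end)] = level
    for sp, s, e in backchannels:
        if sp == speaker:
            amp[(t >= s) & (t < e)] = level
    return np.clip(amp, 0.0, 100.0)


def _rotate_away(
    d: np.ndarray, theta_deg: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Rotate unit vectors ``d`` by ``theta`` degrees about axes
    perpendicular to them (azimuth ``phi`` selects the axis)."""
    theta = np.deg2rad(theta_deg)
    # build an orthonormal frame (d, e1, e2)
    ref = np.zeros_like(d)
    ref[:, 0] = 1.0
    swap = np.abs(d[:, 0]) > 0.9
    ref[swap] = [0.0, 1.0, 0.0]
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    offset_dir = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    out = np.cos(theta)[:, None] * d + np.sin(theta)[:, None] * offset_dir
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _two_state_gaze(
    rng: np.random.Generator,
    n: int,
    dt: float,
    p_target: np.ndarray,
    dwell_s: float,
) -> np.ndarray:
    """Two-state (at-eyes/away) Markov chain with time-varying
    stationary probability ``p_target`` and mean combined dwell time
    ``dwell_s``. Returns a boolean at-eyes array."""
    nu = 1.0 / dwell_s
    state = rng.random() < p_target[0]
    out = np.empty(n, dtype=bool)
    u = rng.random(n)
    for i in range(n):
        p = p_target[i]
        if state:
            if u[i] < nu * (1.0 - p) * dt:
                state = False
        else:
            if u[i] < nu * p * dt:
                state = True
        out[i] = state
    return out


def _smooth_transitions(x: np.ndarray, n_ramp: int) -> np.ndarray:
    """Convert a step signal into one with cosine ramps of ``n_ramp``
    samples at each step (moving-average equivalent smoothing)."""
    if n_ramp <= 1:
        return x.astype(float)
    w = np.hanning(2 * n_ramp + 1)
    w /= w.sum()
    xp = np.pad(x.astype(float), n_ramp, mode="edge")
    return np.convolve(xp, w, mode="same")[n_ramp:-n_ramp]


def _render_gaze(
    rng: np.random.Generator,
    t: np.ndarray,
    own_turn: np.ndarray,
    partner_turn: np.ndarray,
    p_speak: float,
    p_listen: float,
    config: SyntheticConfig,
) -> dict[str, np.ndarray]:
    """Render binocular gaze rays toward/away from the partner's eye
    centers, with blinks, plus the time-varying eye-center targets."""
    n = t.size
    dt = float(t[1] - t[0]) if n > 1 else 1.0 / config.sample_rate_gaze_hz

    # phase-dependent stationary at-eyes probability
    p = np.full(n, 0.5 * (p_speak + p_listen))
    speaking = own_turn & ~partner_turn
    listening = ~own_turn & partner_turn
    p[speaking] = p_speak
    p[listening] = p_listen
    at_eyes = _two_state_gaze(rng, n, dt, p, config.gaze_dwell_s)

    # partner head sway; eye centers 6.4 cm apart at ~1 m distance
    sway = 0.02 * np.sin(2 * np.pi * 0.08 * t + rng.uniform(0, 2 * np.pi))
    head = np.column_stack([sway, np.full(n, 1.45), np.full(n, 1.0)])
    tgt_left = head + np.array([-0.032, 0.0, 0.0])
    tgt_right = head + np.array([0.032, 0.0, 0.0])

    # own eye origins with slight sway
    own_sway = 0.01 * np.sin(2 * np.pi * 0.06 * t + rng.uniform(0, 2 * np.pi))
    origin_l = np.column_stack([own_sway - 0.032, np.full(n, 1.45), np.zeros(n)])
    origin_r = np.column_stack([own_sway + 0.032, np.full(n, 1.45), np.zeros(n)])

    # per-visit offset magnitudes: small inside the at-eyes cone, large
    # outside; the offset azimuth rotates slowly and continuously so the
    # rendered ray has no direction discontinuities
    visit_id = np.concatenate([[0], np.cumsum(np.abs(np.diff(at_eyes.view(np.int8))))])
    n_visits = int(visit_id[-1]) + 1
    small = rng.uniform(0.1, config.at_eyes_max_offset_deg, n_visits)
    large = rng.uniform(*config.away_offset_deg, n_visits)
    which_eye = rng.integers(0, 2, n_visits)  # aimed partner eye per visit

    theta_step = np.where(at_eyes, small[visit_id], large[visit_id])
    jitter = 0.15 * np.sin(2 * np.pi * 0.5 * t + rng.uniform(0, 2 * np.pi))
    n_ramp = max(1, int(round(config.transition_s / dt)))
    theta = _smooth_transitions(theta_step, n_ramp) + jitter
    theta = np.clip(theta, 0.05, None)
    phi = 2 * np.pi * 0.07 * t + rng.uniform(0, 2 * np.pi)

    aim = np.where(which_eye[visit_id][:, None] == 0, tgt_left, tgt_right)
    aim = np.column_stack(
        [_smooth_transitions(aim[:, c], n_ramp) for c in range(3)]
    )

    def rays(origin: np.ndarray, extra_deg: float) -> np.ndarray:
        d = aim - origin
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return _rotate_away(d, theta + extra_deg, phi)

    dir_l = rays(origin_l, 0.0)
    dir_r = rays(origin_r, rng.uniform(-0.1, 0.1))

    # ground-truth at-eyes: minimum angle of any rendered ray (left,
    # right, cyclopean) to either partner eye center, before blink
    # corruption
    def angle(origin: np.ndarray, d: np.ndarray, tgt: np.ndarray) -> np.ndarray:
        v = tgt - origin
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return np.degrees(np.arccos(np.clip(np.sum(d * v, axis=1), -1.0, 1.0)))

    origin_c = 0.5 * (origin_l + origin_r)
    dir_c = dir_l + dir_r
    dir_c /= np.linalg.norm(dir_c, axis=1, keepdims=True)
    min_angle = np.min(
        np.column_stack(
            [
                angle(o, d, g)
                for o, d in ((origin_l, dir_l), (origin_r, dir_r), (origin_c, dir_c))
                for g in (tgt_left, tgt_right)
            ]
        ),
        axis=1,
    )
    truth_at_eyes = min_angle <= 2.0

    # blinks: Poisson onsets, fixed closure duration; gaze rays are
    # corrupted (rotated far downward) while the lids are closed
    blink = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(config.blink_rate_hz * t[-1]) if n > 1 else 0
    onsets = np.sort(rng.uniform(0, max(t[-1] - config.blink_duration_s, 0), n_blinks))
    for s in onsets:
        blink[(t >= s) & (t < s + config.blink_duration_s)] = True
    corrupt = _rotate_away(
        dir_l[blink], np.full(blink.sum(), 25.0), np.full(blink.sum(), -np.pi / 2)
    )
    dir_l = dir_l.copy()
    dir_r = dir_r.copy()
    dir_l[blink] = corrupt
    dir_r[blink] = corrupt

    return {
        "origin_l": origin_l,
        "origin_r": origin_r,
        "dir_l": dir_l,
        "dir_r": dir_r,
        "blink": blink,
        "tgt_left": tgt_left,
        "tgt_right": tgt_right,
        "truth_at_eyes": truth_at_eyes,
        "speaking": speaking,
        "listening": listening,
    }


def _render_face(
    rng: np.random.Generator,
    t: np.ndarray,
    topic_bounds: list[tuple[float, float]],
    smiling_targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mouth-corner action-unit traces whose per-topic mean smile score
    equals the (non-negative part of the) per-topic target."""
    raw = 1.0 + np.abs(rng.normal(0.0, 0.5, t.size))
    # smile events: Poisson onsets, ~2 s duration, amplitude 30
    n_ev = rng.poisson(0.06 * t[-1]) if t.size > 1 else 0
    for s in np.sort(rng.uniform(0, max(t[-1] - 2.0, 0.1), n_ev)):
        raw[(t >= s) & (t < s + rng.uniform(1.0, 3.0))] += 30.0
    trace = np.zeros_like(raw)
    for (lo, hi), target in zip(topic_bounds, smiling_targets):
        m = (t >= lo) & (t < hi)
        if not m.any():
            continue
        target = max(0.0, target)
        seg = raw[m] * (target / raw[m].mean())
        # clipping at 100 would bias the mean low; restore it additively
        for _ in range(4):
            seg = np.clip(seg, 0.0, 100.0)
            seg = seg + (target - seg.mean())
        trace[m] = np.clip(seg, 0.0, 100.0)
    asym = 0.08 * np.sin(2 * np.pi * 0.03 * t + rng.uniform(0, 2 * np.pi))
    au_left = np.clip(trace * (1.0 + asym), 0.0, 100.0)
    au_right = np.clip(trace * (1.0 - asym), 0.0, 100.0)
    return au_left, au_right


def _render_rr(
    rng: np.random.Generator,
    topic_bounds: list[tuple[float, float]],
    hr_targets: np.ndarray,
    hf_targets: np.ndarray,
    config: SyntheticConfig,
) -> np.ndarray:
    """Beat times over the whole session. The RR level is mean RR (from
    the heart-rate target) plus a sinusoid at the respiratory frequency
    whose amplitude realizes the HF-HRV target (log ms^2; power A^2/2),
    plus white noise. Targets drift smoothly between topic midpoints —
    heart rate does not step discontinuously at topic boundaries."""
    phase = rng.uniform(0, 2 * np.pi)
    mids = np.array([0.5 * (lo + hi) for lo, hi in topic_bounds])
    mean_rr_knots = 60000.0 / np.clip(np.asarray(hr_targets, dtype=float), 40.0, 180.0)
    amp_knots = np.sqrt(
        2.0 * np.exp(np.clip(np.asarray(hf_targets, dtype=float), 2.0, 8.5))
    )
    beats = [0.0]
    t = 0.0
    end = topic_bounds[-1][1]
    while t < end:
        mean_rr = float(np.interp(t, mids, mean_rr_knots))
        amp = float(np.interp(t, mids, amp_knots))
        rr = (
            mean_rr
            + amp * math.sin(2 * math.pi * config.resp_freq_hz * t + phase)
            + rng.normal(0.0, config.rr_noise_ms)
        )
        rr = float(np.clip(rr, 320.0, 1980.0))
        t += rr / 1000.0
        if t < end:
            beats.append(t)
    return np.asarray(beats)


def _ecg_template(fs: float) -> tuple[np.ndarray, int]:
    """One PQRST complex sampled at ``fs``; returns the waveform and
    the index of the R peak within it."""
    tt = np.arange(-0.30, 0.45, 1.0 / fs)

    def g(mu: float, sigma: float, a: float) -> np.ndarray:
        return a * np.exp(-0.5 * ((tt - mu) / sigma) ** 2)

    wave = (
        g(-0.12, 0.025, 0.10)  # P
        + g(-0.025, 0.008, -0.15)  # Q
        + g(0.0, 0.011, 1.2)  # R
        + g(0.028, 0.009, -0.25)  # S
        + g(0.18, 0.040, 0.30)  # T
    )
    return wave, int(np.argmin(np.abs(tt)))


def synthesize_ecg(
    beat_times: np.ndarray,
    duration_s: float,
    fs: float = 1000.0,
    snr_db: float = 20.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a template-based ECG trace (mV) from R-peak times.

    Returns ``(t, mv)`` where white noise is added at the requested
    signal-to-noise ratio (``snr_db=inf`` gives a clean trace).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    wave, r_idx = _ecg_template(fs)
    for bt in beat_times:
        i0 = int(round(bt * fs)) - r_idx
        lo, hi = max(i0, 0), min(i0 + wave.size, n)
        if hi > lo:
            sig[lo:hi] += wave[lo - i0 : hi - i0]
    if np.isfinite(snr_db):
        p_sig = float(np.mean(sig**2))
        sigma = math.sqrt(p_sig / (10.0 ** (snr_db / 10.0)))
        sig = sig + rng.normal(0.0, sigma, n)
    return t, sig


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------


def _clip_targets(row: pd.Series) -> dict[str, float]:
    """Physical clipping applied when targets are rendered as streams."""
    return {
        "gaze_speaking": float(np.clip(row["gaze_speaking"], 2.0, 98.0)),
        "gaze_listening": float(np.clip(row["gaze_listening"], 2.0, 98.0)),
        "smiling": float(np.clip(row["smiling"], 0.5, 90.0)),
        "speaking_pct": float(np.clip(row["speaking_pct"], 10.0, 90.0)),
        "interrupting_pct": float(np.clip(row["interrupting_pct"], 0.2, 25.0)),
        "mean_gap_s": float(np.clip(row["mean_gap_s"], 0.45, 4.0)),
        "loudness": float(np.clip(row["loudness"], 2.05, 50.0)),
        "heart_rate_bpm": float(np.clip(row["heart_rate_bpm"], 45.0, 170.0))
        if np.isfinite(row["heart_rate_bpm"])
        else np.nan,
        "hf_hrv": float(np.clip(row["hf_hrv"], 2.5, 8.4))
        if np.isfinite(row["hf_hrv"])
        else np.nan,
    }


def generate_session(
    dyad_traits: tuple[TraitProfile, TraitProfile],
    targets: pd.DataFrame,
    config: SyntheticConfig,
    seed: int,
) -> dict:
    """Generate all raw streams of one dyadic session.

    ``targets`` holds the per-topic measure targets of both
    participants (rows ``participant x topic``). Returns a dict with,
    per participant id: ``gaze``, ``targets``, ``audio``, ``face``
    DataFrames, beat times (or ``None`` for missing-ECG participants),
    plus scheduling truth for testing.
    """
    rng = np.random.default_rng(seed)
    pids = [p.participant_id for p in dyad_traits]
    k = config.topics_per_session
    dur = config.topic_duration_s
    topic_bounds = [(i * dur, (i + 1) * dur) for i in range(k)]
    session_len = k * dur

    clipped = {
        pid: [
            _clip_targets(
                targets[(targets.participant == pid) & (targets.topic == t)].iloc[0]
            )
            for t in range(k)
        ]
        for pid in pids
    }
    missing_ecg = set(targets.attrs.get("missing_ecg", []))

    # --- conversation schedule (session clock) ---
    all_turns: list[_Turn] = []
    all_bc: list[tuple[int, float, float]] = []
    truth_speech = {pid: [] for pid in pids}
    for t_idx, (lo, _) in enumerate(topic_bounds):
        share = [clipped[pid][t_idx]["speaking_pct"] / 100.0 for pid in pids]
        mean_turn = tuple(
            max(config.min_turn_s + 0.3, 2.0 * config.mean_turn_s * s) for s in share
        )
        gap_mean = tuple(clipped[pid][t_idx]["mean_gap_s"] for pid in pids)
        # convert target overlap share into a per-transfer interruption
        # probability given the expected number of floor transfers
        cycle = sum(mean_turn) / 2.0 + float(np.mean(gap_mean))
        transfers = max(1.0, dur / (2.0 * cycle))
        p_int = tuple(
            float(
                np.clip(
                    clipped[pid][t_idx]["interrupting_pct"]
                    / 100.0
                    * dur
                    / (transfers * config.overlap_mean_s),
                    0.01,
                    0.85,
                )
            )
            for pid in pids
        )
        turns, bcs = _schedule_topic(rng, dur, mean_turn, gap_mean, p_int, config)
        truth = _speech_truth(turns, dur)
        for sp, pid in enumerate(pids):
            truth_speech[pid].append(truth[sp])
        all_turns.extend(_Turn(tu.speaker, tu.start + lo, tu.end + lo, tu.interruption) for tu in turns)
        all_bc.extend((sp, s + lo, e + lo) for sp, s, e in bcs)

    # --- audio ---
    dt_a = 1.0 / config.sample_rate_audio_hz
    t_audio = np.arange(int(round(session_len / dt_a))) * dt_a
    audio = {}
    for sp, pid in enumerate(pids):
        amp = np.zeros_like(t_audio)
        for t_idx, (lo, hi) in enumerate(topic_bounds):
            m = (t_audio >= lo) & (t_audio < hi)
            sub_turns = [tu for tu in all_turns if lo <= tu.start < hi]
            sub_bc = [b for b in all_bc if lo <= b[1] < hi]
            amp[m] = _render_amplitude(
                t_audio[m],
                sub_turns,
                sub_bc,
                sp,
                clipped[pid][t_idx]["loudness"],
                rng,
            )
        audio[pid] = pd.DataFrame({"t_s": t_audio, "amplitude": amp})

    # --- gaze ---
    dt_g = 1.0 / config.sample_rate_gaze_hz
    t_gaze = np.arange(int(round(session_len / dt_g))) * dt_g
    gaze = {}
    gaze_targets = {}
    truth_gaze = {pid: [] for pid in pids}
    blink_budget = {}
    for sp, pid in enumerate(pids):
        own = np.zeros(t_gaze.size, dtype=bool)
        partner = np.zeros(t_gaze.size, dtype=bool)
        for tu in all_turns:
            m = (t_gaze >= tu.start) & (t_gaze < tu.end)
            if tu.speaker == sp:
                own |= m
            else:
                partner |= m
        # use session-mean gaze targets for the switching process, per
        # topic for the truth bookkeeping
        pieces = []
        for t_idx, (lo, hi) in enumerate(topic_bounds):
            m = (t_gaze >= lo) & (t_gaze < hi)
            r = _render_gaze(
                rng,
                t_gaze[m] - lo,
                own[m],
                partner[m],
                clipped[pid][t_idx]["gaze_speaking"] / 100.0,
                clipped[pid][t_idx]["gaze_listening"] / 100.0,
                config,
            )
            sp_m, li_m = r["speaking"], r["listening"]
            truth_gaze[pid].append(
                {
                    "gaze_speaking": 100.0 * r["truth_at_eyes"][sp_m].mean()
                    if sp_m.any()
                    else np.nan,
                    "gaze_listening": 100.0 * r["truth_at_eyes"][li_m].mean()
                    if li_m.any()
                    else np.nan,
                }
            )
            pieces.append(r)
        cat = {
            key: np.concatenate([p[key] for p in pieces])
            for key in ("origin_l", "origin_r", "dir_l", "dir_r", "tgt_left", "tgt_right")
        }
        blink = np.concatenate([p["blink"] for p in pieces])
        pad = 0.1
        masked = np.zeros_like(blink)
        for i in np.flatnonzero(blink):
            masked |= np.abs(t_gaze - t_gaze[i]) <= pad + 1e-9
        blink_budget[pid] = 100.0 * masked.mean()
        gaze[pid] = pd.DataFrame(
            {
                "t_s": t_gaze,
                "lx": cat["origin_l"][:, 0],
                "ly": cat["origin_l"][:, 1],
                "lz": cat["origin_l"][:, 2],
                "ldx": cat["dir_l"][:, 0],
                "ldy": cat["dir_l"][:, 1],
                "ldz": cat["dir_l"][:, 2],
                "rx": cat["origin_r"][:, 0],
                "ry": cat["origin_r"][:, 1],
                "rz": cat["origin_r"][:, 2],
                "rdx": cat["dir_r"][:, 0],
                "rdy": cat["dir_r"][:, 1],
                "rdz": cat["dir_r"][:, 2],
                "blink": blink.astype(int),
            }
        )
        gaze_targets[pid] = pd.DataFrame(
            {
                "t_s": t_gaze,
                "left_x": cat["tgt_left"][:, 0],
                "left_y": cat["tgt_left"][:, 1],
                "left_z": cat["tgt_left"][:, 2],
                "right_x": cat["tgt_right"][:, 0],
                "right_y": cat["tgt_right"][:, 1],
                "right_z": cat["tgt_right"][:, 2],
            }
        )

    # --- face ---
    dt_f = 1.0 / config.sample_rate_face_hz
    t_face = np.arange(int(round(session_len / dt_f))) * dt_f
    face = {}
    for pid in pids:
        au_l, au_r = _render_face(
            rng,
            t_face,
            topic_bounds,
            np.array([clipped[pid][t]["smiling"] for t in range(k)]),
        )
        face[pid] = pd.DataFrame({"t_s": t_face, "au_left": au_l, "au_right": au_r})

    # --- cardiac ---
    beats = {}
    for pid in pids:
        if pid in missing_ecg:
            beats[pid] = None
            continue
        beats[pid] = _render_rr(
            rng,
            topic_bounds,
            np.array([clipped[pid][t]["heart_rate_bpm"] for t in range(k)]),
            np.array([clipped[pid][t]["hf_hrv"] for t in range(k)]),
            config,
        )

    turn_truth = pd.DataFrame(
        [
            {
                "speaker": pids[tu.speaker],
                "start_s": tu.start,
                "end_s": tu.end,
                "interruption": tu.interruption,
            }
            for tu in sorted(all_turns, key=lambda x: x.start)
        ]
    )
    return {
        "participants": pids,
        "topic_bounds": topic_bounds,
        "gaze": gaze,
        "gaze_targets": gaze_targets,
        "audio": audio,
        "face": face,
        "beats": beats,
        "truth": {
            "speech": truth_speech,
            "gaze": truth_gaze,
            "turns": turn_truth,
            "blink_budget_pct": blink_budget,
            "clipped_targets": clipped,
        },
    }


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8f")


def generate_study(
    config: SyntheticConfig, outdir: str | Path
) -> dict:
    """Generate a full synthetic study under ``outdir``.

    Writes one directory per dyad (``dyad_000`` ...) containing
    ``gaze_<pid>.csv``, ``targets_<pid>.csv``, ``audio_<pid>.csv``,
    ``face_<pid>.csv`` and ``rr_<pid>.csv`` (or ``ecg_<pid>.csv`` in
    ``full_ecg`` mode), plus a study-level ``traits.csv`` and
    ``manifest.json``. Returns the manifest dict.
    """
    config.validate()
    if config.n_dyads < 1:
        raise ValueError("n_dyads must be >= 1: empty study")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(config.seed)
    profiles = sample_traits(config, np.random.default_rng(config.seed))
    targets = sample_behavior_targets(
        profiles, config, np.random.default_rng(config.seed + 1)
    )

    traits_df = pd.DataFrame(
        [{"participant_id": p.participant_id, **p.scale_scores} for p in profiles]
    )
    _write_csv(traits_df, outdir / "traits.csv")

    manifest: dict = {
        "seed": config.seed,
        "n_dyads": config.n_dyads,
        "topics_per_session": config.topics_per_session,
        "topic_duration_s": config.topic_duration_s,
        "ecg_mode": config.ecg_mode,
        "measures": list(MEASURES),
        "traits": list(TRAIT_NAMES),
        "effect_matrix": config.effect_matrix.tolist(),
        "trait_correlations": config.trait_correlations.tolist(),
        "missing_ecg": targets.attrs.get("missing_ecg", []),
        "latents": {
            p.participant_id: [p.latent_sa, p.latent_p, p.latent_v] for p in profiles
        },
        "topic_bounds": [
            [i * config.topic_duration_s, (i + 1) * config.topic_duration_s]
            for i in range(config.topics_per_session)
        ],
        "dyads": [],
        "truth": {},
    }

    session_seeds = root_rng.integers(0, 2**31 - 1, size=config.n_dyads)
    for d in range(config.n_dyads):
        pa, pb = profiles[2 * d], profiles[2 * d + 1]
        ddir = outdir / f"dyad_{d:03d}"
        ddir.mkdir(exist_ok=True)
        sub = targets[targets.participant.isin([pa.participant_id, pb.participant_id])]
        sub = sub.copy()
        sub.attrs["missing_ecg"] = targets.attrs.get("missing_ecg", [])
        sess = generate_session((pa, pb), sub, config, int(session_seeds[d]))
        for pid in sess["participants"]:
            _write_csv(sess["gaze"][pid], ddir / f"gaze_{pid}.csv")
            _write_csv(sess["gaze_targets"][pid], ddir / f"targets_{pid}.csv")
            _write_csv(sess["audio"][pid], ddir / f"audio_{pid}.csv")
            _write_csv(sess["face"][pid], ddir / f"face_{pid}.csv")
            bt = sess["beats"][pid]
            if bt is None:
                continue
            if config.ecg_mode == "rr_only":
                _write_csv(
                    pd.DataFrame({"r_peak_time_s": bt}), ddir / f"rr_{pid}.csv"
                )
            else:
                dur = config.topics_per_session * config.topic_duration_s
                t_e, mv = synthesize_ecg(
                    bt,
                    dur,
                    config.ecg_sample_rate_hz,
                    config.ecg_snr_db,
                    np.random.default_rng(int(session_seeds[d]) + 17),
                )
                _write_csv(pd.DataFrame({"t_s": t_e, "mv": mv}), ddir / f"ecg_{pid}.csv")
        manifest["dyads"].append(
            {
                "dyad_id": d,
                "dir": ddir.name,
                "participants": sess["participants"],
            }
        )
        manifest["truth"][str(d)] = {
            "speech": sess["truth"]["speech"],
            "gaze": sess["truth"]["gaze"],
            "blink_budget_pct": sess["truth"]["blink_budget_pct"],
            "clipped_targets": sess["truth"]["clipped_targets"],
        }

    targets_long = targets.copy()
    _write_csv(targets_long, outdir / "true_targets.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
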