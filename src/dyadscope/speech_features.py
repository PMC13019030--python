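"""Turn-taking segmentation of dyadic amplitude streams.

Voicing is amplitude strictly above a threshold of 2 (on the 0-100
microphone scale). Maximal voiced runs separated by pauses of at most
2 s are fused into one speech segment *before* duration classification;
fused segments shorter than 1 s are backchannels, all others speaking
turns. A turn that starts while the partner is inside a turn is an
interruption, attributed to the participant who began speaking while
previously listening. Per-sample conversational phases (speaking /
listening / overlap / silence) partition the session, with backchannels
transparent to phases and interruptions. Floor-transfer gaps are the
non-negative lags between one speaker's turn end and the other's next
turn start.

All intervals are half-open ``[start, end)`` in seconds; a sample at
time ``t`` covers ``[t, t + dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "TurnTable",
    "PhaseTrack",
    "SpeechSummary",
    "detect_voiced",
    "segment_speaker",
    "build_turn_table",
    "compute_gaps",
    "summarize_speech",
    "analyze_dyad",
]

PHASE_SPEAKING = 0
PHASE_LISTENING = 1
PHASE_OVERLAP = 2
PHASE_SILENCE = 3
PHASE_NAMES = {0: "speaking", 1: "listening", 2: "overlap", 3: "silence"}


@dataclass(frozen=True)
class Segment:
    speaker: int
    start: float
    end: float
    kind: str  # "turn" | "backchannel"
    interruption: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TurnTable:
    segments: list[Segment]

    def turns(self, speaker: int | None = None) -> list[Segment]:
        return [
            s
            for s in self.segments
            if s.kind == "turn" and (speaker is None or s.speaker == speaker)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "speaker": s.speaker,
                    "start_s": s.start,
                    "end_s": s.end,
                    "kind": s.kind,
                    "interruption": s.interruption,
                }
                for s in sorted(self.segments, key=lambda s: (s.start, s.speaker))
            ]
        )


@dataclass
class PhaseTrack:
    """Per-sample conversational phase of each participant (codes
    ``PHASE_*``) on the common audio clock."""

    t: np.ndarray
    phases: tuple[np.ndarray, np.ndarray]

    def masks(self, speaker: int) -> dict[str, np.ndarray]:
        ph = self.phases[speaker]
        return {name: ph == code for code, name in PHASE_NAMES.items()}

    def masks_at(self, times: np.ndarray, speaker: int) -> dict[str, np.ndarray]:
        """Phase masks nearest-neighbor resampled onto another clock."""
        idx = np.clip(np.searchsorted(self.t, times), 1, self.t.size - 1)
        idx = idx - (np.abs(self.t[idx - 1] - times) <= np.abs(self.t[idx] - times))
        ph = self.phases[speaker][idx]
        return {name: ph == code for code, name in PHASE_NAMES.items()}


@dataclass
class SpeechSummary:
    speaking_pct: float
    interrupting_pct: float
    mean_gap_s: float
    loudness: float
    n_turns: int
    n_backchannels: int


def detect_voiced(amplitude: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Voiced iff amplitude strictly exceeds the threshold."""
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude < 0) or np.any(amplitude > 100):
        raise ValueError("amplitude must be on the 0-100 scale")
    return amplitude > threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True values."""
    m = np.asarray(mask, dtype=bool).astype(np.int8)
    d = np.diff(np.concatenate([[0], m, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def segment_speaker(
    voiced: np.ndarray,
    t: np.ndarray,
    speaker: int = 0,
    min_turn_s: float = 1.0,
    max_pause_s: float = 2.0,
) -> list[Segment]:
    """Segment one participant's voicing mask into turns and
    backchannels.

    Raw voiced runs with inter-run silence <= ``max_pause_s`` are fused
    first; fused segments with duration < ``min_turn_s`` become
    backchannels, the rest turns (interruption flags are assigned later
    by :func:`build_turn_table`).
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        return []
    dt = float(np.median(np.diff(t)))
    raw = [(t[a], t[b - 1] + dt) for a, b in _runs(voiced)]
    if not raw:
        return []
    fused: list[list[float]] = [list(raw[0])]
    for s, e in raw[1:]:
        if s - fused[-1][1] <= max_pause_s + 1e-9:
            fused[-1][1] = e
        else:
            fused.append([s, e])
    return [
        Segment(
            speaker,
            s,
            e,
            "backchannel" if (e - s) < min_turn_s - 1e-9 else "turn",
        )
        for s, e in fused
    ]


def build_turn_table(
    segments_a: list[Segment],
    segments_b: list[Segment],
    t: np.ndarray,
) -> tuple[TurnTable, PhaseTrack]:
    """Merge per-speaker segments, attribute interruptions, and build
    the per-sample phase partition on the common clock ``t``.

    A turn whose onset falls inside a partner turn is flagged as an
    interruption of the later starter (simultaneous onsets within one
    sample period are attributed to the lower participant index).
    Backchannels neither create speaking/overlap phases nor trigger
    interruptions.
    """
    t = np.asarray(t, dtype=float)
    turns_a = [s for s in segments_a if s.kind == "turn"]
    turns_b = [s for s in segments_b if s.kind == "turn"]

    def flag(own: list[Segment], other: list[Segment]) -> list[Segment]:
        out = []
        for s in own:
            inside = any(o.start < s.start < o.end for o in other)
            if not inside:
                # simultaneous-onset tie: later index yields
                tie = any(
                    abs(o.start - s.start) < 1e-9 and s.speaker > o.speaker
                    for o in other
                )
                inside = tie
            out.append(Segment(s.speaker, s.start, s.end, s.kind, inside))
        return out

    turns_a = flag(turns_a, turns_b)
    turns_b = flag(turns_b, turns_a)
    segments = (
        turns_a
        + turns_b
        + [s for s in segments_a + segments_b if s.kind == "backchannel"]
    )

    def in_turn(turns: list[Segment]) -> np.ndarray:
        mask = np.zeros(t.size, dtype=bool)
        for s in turns:
            mask |= (t >= s.start - 1e-9) & (t < s.end - 1e-9)
        return mask

    a_in, b_in = in_turn(turns_a), in_turn(turns_b)
    phase_a = np.full(t.size, PHASE_SILENCE, dtype=np.int8)
    phase_b = np.full(t.size, PHASE_SILENCE, dtype=np.int8)
    phase_a[a_in & ~b_in] = PHASE_SPEAKING
    phase_a[a_in & b_in] = PHASE_OVERLAP
    phase_a[~a_in & b_in] = PHASE_LISTENING
    phase_b[b_in & ~a_in] = PHASE_SPEAKING
    phase_b[b_in & a_in] = PHASE_OVERLAP
    phase_b[~b_in & a_in] = PHASE_LISTENING
    return TurnTable(segments), PhaseTrack(t, (phase_a, phase_b))


def compute_gaps(table: TurnTable) -> dict[int, list[float]]:
    """Floor-transfer gaps per participant.

    For every pair of consecutive turns (ordered by onset) where the
    floor passes from the partner to the participant with no
    intervening turn, the gap is ``own start - partner end``; negative
    lags (interruptions) are excluded.
    """
    ordered = sorted(table.turns(), key=lambda s: (s.start, s.speaker))
    gaps: dict[int, list[float]] = {0: [], 1: []}
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.speaker != prev.speaker and cur.start >= prev.end:
            gaps[cur.speaker].append(cur.start - prev.end)
    return gaps


def summarize_speech(
    table: TurnTable,
    phases: PhaseTrack,
    amplitude: np.ndarray,
    speaker: int,
    threshold: float = 2.0,
) -> SpeechSummary:
    """Speaking-behavior summary for one participant.

    speaking_pct is the participant's share of the combined dyad turn
    time; interrupting_pct is the share of session time spent in
    overlap that the participant's own (interrupting) turn initiated;
    loudness is the mean amplitude over the participant's voiced
    samples inside their turns.
    """
    t = phases.t
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    own = table.turns(speaker)
    other = table.turns(1 - speaker)
    own_time = sum(s.duration for s in own)
    other_time = sum(s.duration for s in other)
    total = own_time + other_time
    speaking_pct = 100.0 * own_time / total if total > 0 else float("nan")

    # overlap time attributed to own interrupting turns
    intr = 0.0
    for s in own:
        if not s.interruption:
            continue
        for o in other:
            lo, hi = max(s.start, o.start), min(s.end, o.end)
            if hi > lo and o.start <= s.start:
                intr += hi - lo
    session = t[-1] + dt - t[0] if t.size > 1 else 0.0
    interrupting_pct = 100.0 * intr / session if session > 0 else float("nan")

    gaps = compute_gaps(table)[speaker]
    mean_gap = float(np.mean(gaps)) if gaps else float("nan")

    amplitude = np.asarray(amplitude, dtype=float)
    in_own = np.zeros(t.size, dtype=bool)
    for s in own:
        in_own |= (t >= s.start - 1e-9) & (t < s.end - 1e-9)
    voiced_in_turn = in_own & (amplitude > threshold)
    loudness = (
        float(amplitude[voiced_in_turn].mean()) if voiced_in_turn.any() else float("nan")
    )
    n_bc = sum(
        1 for s in table.segments if s.kind == "backchannel" and s.speaker == speaker
    )
    return SpeechSummary(
        speaking_pct, interrupting_pct, mean_gap, loudness, len(own), n_bc
    )


def analyze_dyad(
    t: np.ndarray,
    amplitude_a: np.ndarray,
    amplitude_b: np.ndarray,
    threshold: float = 2.0,
    min_turn_s: float = 1.0,
    max_pause_s: float = 2.0,
) -> tuple[TurnTable, PhaseTrack, tuple[SpeechSummary, SpeechSummary]]:
    """Full speech analysis of one dyad on a common clock."""
    t = np.asarray(t, dtype=float)
    seg_a = segment_speaker(
        detect_voiced(amplitude_a, threshold), t, 0, min_turn_s, max_pause_s
    )
    seg_b = segment_speaker(
        detect_voiced(amplitude_b, threshold), t, 1, min_turn_s, max_pause_s
    )
    table, phases = build_turn_table(seg_a, seg_b, t)
    sum_a = summarize_speech(table, phases, amplitude_a, 0, threshold)
    sum_b = summarize_speech(table, phases, amplitude_b, 1, threshold)
    return table, phases, (sum_a, sum_b)
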