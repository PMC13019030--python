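"""Independent brute-force reference implementations used as test
oracles. Everything here is written as plain per-sample / per-element
loops, deliberately sharing no code with the package."""

from __future__ import annotations

import numpy as np


def oracle_segments(amp, t, speaker, threshold=2.0, min_turn=1.0, max_pause=2.0):
    """Per-sample run scan -> pause fusion -> duration classification."""
    n = len(t)
    dt = t[1] - t[0]
    voiced = [float(a) > threshold for a in amp]
    runs = []
    i = 0
    while i < n:
        if voiced[i]:
            j = i
            while j < n and voiced[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    fused = []
    for a, b in runs:
        if fused and (t[a] - (t[fused[-1][1] - 1] + dt)) <= max_pause + 1e-9:
            fused[-1][1] = b
        else:
            fused.append([a, b])
    segs = []
    for a, b in fused:
        start, end = t[a], t[b - 1] + dt
        kind = "backchannel" if (end - start) < min_turn - 1e-9 else "turn"
        segs.append({"speaker": speaker, "start": start, "end": end, "kind": kind})
    return segs


def oracle_dyad(t, amp_a, amp_b, threshold=2.0, min_turn=1.0, max_pause=2.0):
    """Full per-sample state-machine analysis of one dyad.

    Returns segments with interruption flags, per-sample phase code
    arrays (0 speaking, 1 listening, 2 overlap, 3 silence), gap lists,
    and summary quantities per speaker.
    """
    n = len(t)
    dt = t[1] - t[0]
    segs = {
        0: oracle_segments(amp_a, t, 0, threshold, min_turn, max_pause),
        1: oracle_segments(amp_b, t, 1, threshold, min_turn, max_pause),
    }
    # interruption flags: onset strictly inside a partner turn; exactly
    # simultaneous onsets are attributed to the higher participant index
    for sp in (0, 1):
        for s in segs[sp]:
            s["interruption"] = False
            if s["kind"] != "turn":
                continue
            for o in segs[1 - sp]:
                if o["kind"] != "turn":
                    continue
                if o["start"] < s["start"] < o["end"]:
                    s["interruption"] = True
                elif abs(o["start"] - s["start"]) < 1e-9 and sp > (1 - sp):
                    s["interruption"] = True

    in_turn = {0: [False] * n, 1: [False] * n}
    turn_start = {0: [None] * n, 1: [None] * n}
    for sp in (0, 1):
        for s in segs[sp]:
            if s["kind"] != "turn":
                continue
            for i in range(n):
                if s["start"] - 1e-9 <= t[i] < s["end"] - 1e-9:
                    in_turn[sp][i] = True
                    turn_start[sp][i] = s["start"]

    phases = {0: np.empty(n, dtype=int), 1: np.empty(n, dtype=int)}
    for i in range(n):
        a, b = in_turn[0][i], in_turn[1][i]
        phases[0][i] = 0 if (a and not b) else 2 if (a and b) else 1 if b else 3
        phases[1][i] = 0 if (b and not a) else 2 if (a and b) else 1 if a else 3

    # overlap samples attributed to the later-starting current turn
    intr_time = {0: 0.0, 1: 0.0}
    for i in range(n):
        if in_turn[0][i] and in_turn[1][i]:
            if turn_start[0][i] > turn_start[1][i]:
                intr_time[0] += dt
            elif turn_start[1][i] > turn_start[0][i]:
                intr_time[1] += dt
            else:  # simultaneous onsets: higher index interrupted
                intr_time[1] += dt

    # floor-transfer gaps
    ordered = sorted(
        [s for sp in (0, 1) for s in segs[sp] if s["kind"] == "turn"],
        key=lambda s: (s["start"], s["speaker"]),
    )
    gaps = {0: [], 1: []}
    for prev, cur in zip(ordered, ordered[1:]):
        if cur["speaker"] != prev["speaker"] and cur["start"] >= prev["end"]:
            gaps[cur["speaker"]].append(cur["start"] - prev["end"])

    amps = {0: amp_a, 1: amp_b}
    summaries = {}
    session = n * dt
    turn_time = {
        sp: sum(s["end"] - s["start"] for s in segs[sp] if s["kind"] == "turn")
        for sp in (0, 1)
    }
    for sp in (0, 1):
        total = turn_time[0] + turn_time[1]
        voiced_amp = [
            float(amps[sp][i])
            for i in range(n)
            if in_turn[sp][i] and float(amps[sp][i]) > threshold
        ]
        summaries[sp] = {
            "speaking_pct": 100.0 * turn_time[sp] / total if total > 0 else np.nan,
            "interrupting_pct": 100.0 * intr_time[sp] / session,
            "mean_gap_s": float(np.mean(gaps[sp])) if gaps[sp] else np.nan,
            "loudness": float(np.mean(voiced_amp)) if voiced_amp else np.nan,
        }
    return {"segments": segs, "phases": phases, "gaps": gaps, "summaries": summaries}


def random_dyad_amplitudes(rng, n, p_switch=0.08, p_blip=0.01):
    """Random telegraph-style amplitude pair with speech levels, brief
    blips, exact-threshold samples, and frequent overlap."""
    amps = []
    for _ in range(2):
        amp = np.zeros(n)
        talking = rng.random() < 0.5
        level = rng.uniform(2.2, 8.0)
        for i in range(n):
            if rng.random() < p_switch:
                talking = not talking
                level = rng.uniform(2.2, 8.0)
            if talking:
                amp[i] = level
            elif rng.random() < p_blip:
                amp[i] = rng.uniform(2.2, 8.0)  # isolated blip
            elif rng.random() < 0.02:
                amp[i] = 2.0  # exactly at threshold: must stay unvoiced
            else:
                amp[i] = rng.uniform(0.0, 1.9)
        amps.append(amp)
    return amps[0], amps[1]


def oracle_bh(p):
    """Quadratic-time Benjamini-Hochberg adjusted p-values."""
    p = list(map(float, p))
    m = len(p)
    adj = []
    for pi in p:
        best = 1.0
        for pj in p:
            if pj >= pi:
                rank = sum(1 for pk in p if pk <= pj)
                best = min(best, min(1.0, pj * m / rank))
        adj.append(best)
    return np.array(adj)


def oracle_power_iteration(corr, iters=2000):
    """Leading eigenvector of a symmetric PSD matrix by power iteration."""
    v = np.ones(corr.shape[0]) / np.sqrt(corr.shape[0])
    for _ in range(iters):
        w = corr @ v
        v = w / np.linalg.norm(w)
    return v
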