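"""Pipeline configuration and orchestration.

Ties the stages together: simulate a synthetic study, extract the nine
behavioral/physiological measures per participant and topic (speech
segmentation first, since gaze summaries need the conversational
phases), then fit the trait-association models and similarity analysis.
All interchange is plain CSV with documented headers; intervals are
half-open ``[start, end)`` seconds from session start.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import (
    association_stats,
    cardiac_features,
    face_features,
    gaze_features,
    speech_features,
    synthetic_dyads,
    trait_factors,
)
from .synthetic_dyads import MEASURES, TRAIT_NAMES, SyntheticConfig

logger = logging.getLogger("dyadscope")

__all__ = ["PipelineConfig", "run_simulate", "run_extract", "run_model", "format_report"]


@dataclass
class PipelineConfig:
    """All analysis thresholds and constants, with their standard
    defaults (blink guard 100 ms, 2-degree at-eyes cone, 2nd-order
    10 Hz Butterworth, amplitude threshold 2, 1 s minimum turn, 2 s
    pause fusion, 30 s Welch windows at 50% overlap, 0.15-0.4 Hz HF
    band, 4 Hz RR resampling, 3-SD winsorization, alpha 0.05 with BH
    FDR)."""

    blink_pad_ms: float = 100.0
    gaze_threshold_deg: float = 2.0
    butterworth_order: int = 2
    butterworth_cutoff_hz: float = 10.0
    amp_threshold: float = 2.0
    min_turn_s: float = 1.0
    max_pause_s: float = 2.0
    welch_window_s: float = 30.0
    welch_overlap: float = 0.5
    hf_band_hz: tuple[float, float] = (0.15, 0.4)
    rr_resample_hz: float = 4.0
    winsor_sd: float = 3.0
    alpha: float = 0.05
    fdr: str = "BH"
    cardiac_scope: str = "session"  # "session" | "topic"
    include_interpolated_gaze: bool = True
    include_topic_vc: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["hf_band_hz"] = list(d["hf_band_hz"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "hf_band_hz" in d:
            d["hf_band_hz"] = tuple(d["hf_band_hz"])
        return cls(**d)

    def log_values(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def run_simulate(
    config: SyntheticConfig, outdir: str | Path
) -> dict:
    """Generate a synthetic study (one directory per dyad plus
    traits.csv and manifest.json) under ``outdir``."""
    if config.n_dyads < 1:
        raise ValueError("n_dyads must be >= 1: empty study")
    return synthetic_dyads.generate_study(config, outdir)


def _extract_participant(
    ddir: Path,
    pid: str,
    speaker_idx: int,
    phases: speech_features.PhaseTrack,
    table: speech_features.TurnTable,
    speech: speech_features.SpeechSummary,
    topic_bounds: list[tuple[float, float]],
    config: PipelineConfig,
) -> list[dict]:
    """All nine measures for one participant, one row per topic."""
    rows = []

    # gaze
    gaze_path = ddir / f"gaze_{pid}.csv"
    gaze_ok = gaze_path.exists()
    if gaze_ok:
        stream = gaze_features.load_gaze_csv(gaze_path)
        targets = gaze_features.load_targets_csv(ddir / f"targets_{pid}.csv")
        pre = gaze_features.preprocess(
            stream,
            pad_ms=config.blink_pad_ms,
            cutoff_hz=config.butterworth_cutoff_hz,
            order=config.butterworth_order,
        )
        if pre.valid.sum() >= 2:
            at_eyes = gaze_features.classify_at_eyes(
                pre, targets, threshold_deg=config.gaze_threshold_deg
            )
        else:
            at_eyes = None
        masks = phases.masks_at(pre.t, speaker_idx)
        include = None if config.include_interpolated_gaze else pre.valid

    # face
    face_path = ddir / f"face_{pid}.csv"
    face_df = face_features.load_face_csv(face_path) if face_path.exists() else None

    # cardiac
    rr_path = ddir / f"rr_{pid}.csv"
    ecg_path = ddir / f"ecg_{pid}.csv"
    beats = None
    if rr_path.exists():
        beats = cardiac_features.load_rr_csv(rr_path)
    elif ecg_path.exists():
        t_e, mv = cardiac_features.load_ecg_csv(ecg_path)
        beats = cardiac_features.detect_qrs(t_e, mv)
    if beats is not None and config.cardiac_scope == "session":
        card_session = cardiac_features.summarize_cardiac(beats)

    for t_idx, (lo, hi) in enumerate(topic_bounds):
        row: dict = {"participant": pid, "topic": t_idx}
        # gaze per topic
        if gaze_ok and at_eyes is not None:
            in_topic = (pre.t >= lo) & (pre.t < hi)
            g = gaze_features.summarize_by_phase(
                at_eyes[in_topic],
                masks["speaking"][in_topic],
                masks["listening"][in_topic],
                data_loss_pct=100.0 * (~pre.valid[in_topic]).mean()
                if in_topic.any()
                else float("nan"),
                include_mask=None if include is None else include[in_topic],
            )
            row["gaze_speaking"] = g.pct_at_eyes_speaking
            row["gaze_listening"] = g.pct_at_eyes_listening
            row["data_loss_pct"] = g.data_loss_pct
        else:
            row["gaze_speaking"] = row["gaze_listening"] = float("nan")
            row["data_loss_pct"] = float("nan")

        # speech: per-topic via a per-topic re-analysis is equivalent to
        # slicing the session-level turn table to the topic window
        topic_turns = [
            s
            for s in table.segments
            if s.speaker == speaker_idx or s.speaker == 1 - speaker_idx
        ]
        sub = speech_features.TurnTable(
            [s for s in topic_turns if s.start < hi and s.end > lo]
        )
        in_t = (phases.t >= lo) & (phases.t < hi)
        sub_phases = speech_features.PhaseTrack(
            phases.t[in_t], (phases.phases[0][in_t], phases.phases[1][in_t])
        )
        amp = _AMPLITUDE_CACHE[(ddir, pid)]
        s = speech_features.summarize_speech(
            sub, sub_phases, amp[in_t], speaker_idx, threshold=config.amp_threshold
        )
        row["speaking_pct"] = s.speaking_pct
        row["interrupting_pct"] = s.interrupting_pct
        row["mean_gap_s"] = s.mean_gap_s
        row["loudness"] = s.loudness
        row["n_turns"] = s.n_turns

        # face per topic
        if face_df is not None:
            m = (face_df["t_s"] >= lo) & (face_df["t_s"] < hi)
            if m.any():
                _, mean_score = face_features.smile_intensity(
                    face_df.loc[m, "au_left"].to_numpy(),
                    face_df.loc[m, "au_right"].to_numpy(),
                )
                row["smiling"] = mean_score
            else:
                row["smiling"] = float("nan")
        else:
            row["smiling"] = float("nan")

        # cardiac
        if beats is None:
            row["heart_rate_bpm"] = row["hf_hrv"] = float("nan")
            row["rr_corrections"] = float("nan")
        elif config.cardiac_scope == "session":
            row["heart_rate_bpm"] = card_session.heart_rate_bpm
            row["hf_hrv"] = card_session.hf_hrv
            row["rr_corrections"] = card_session.n_corrected
        else:
            card = cardiac_features.summarize_cardiac(beats, (lo, hi))
            row["heart_rate_bpm"] = card.heart_rate_bpm
            row["hf_hrv"] = card.hf_hrv
            row["rr_corrections"] = card.n_corrected
        rows.append(row)
    return rows


_AMPLITUDE_CACHE: dict = {}


def run_extract(
    session_dir: str | Path, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Extract the behavior matrix (participant x topic x 9 measures)
    from a study directory written by :func:`run_simulate`.

    Missing stream files produce row-level missing values, not
    failures. Extraction is deterministic.
    """
    if config is None:
        config = PipelineConfig()
    config.log_values()
    session_dir = Path(session_dir)
    manifest = json.loads((session_dir / "manifest.json").read_text())
    topic_bounds = [tuple(b) for b in manifest["topic_bounds"]]
    rows: list[dict] = []
    for dyad in manifest["dyads"]:
        ddir = session_dir / dyad["dir"]
        pids = dyad["participants"]
        audio = {}
        for pid in pids:
            df = pd.read_csv(ddir / f"audio_{pid}.csv")
            audio[pid] = (df["t_s"].to_numpy(), df["amplitude"].to_numpy())
        t = audio[pids[0]][0]
        table, phases, summaries = speech_features.analyze_dyad(
            t,
            audio[pids[0]][1],
            audio[pids[1]][1],
            threshold=config.amp_threshold,
            min_turn_s=config.min_turn_s,
            max_pause_s=config.max_pause_s,
        )
        for idx, pid in enumerate(pids):
            _AMPLITUDE_CACHE[(ddir, pid)] = audio[pid][1]
        for idx, pid in enumerate(pids):
            try:
                rows.extend(
                    _extract_participant(
                        ddir, pid, idx, phases, table, summaries[idx],
                        topic_bounds, config,
                    )
                )
            except Exception as exc:  # row-level missingness, not fatal
                logger.warning("extraction failed for %s: %s", pid, exc)
                for t_idx in range(len(topic_bounds)):
                    rows.append(
                        {
                            "participant": pid,
                            "topic": t_idx,
                            **{m: float("nan") for m in MEASURES},
                        }
                    )
        for pid in pids:
            _AMPLITUDE_CACHE.pop((ddir, pid), None)
    df = pd.DataFrame(rows)
    front = ["participant", "topic", *MEASURES]
    extra = [c for c in df.columns if c not in front]
    return df[front + extra]


def run_model(
    summary: pd.DataFrame,
    traits: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Trait factors, winsorized/standardized measures, mixed-model
    associations with BH FDR, and cross-trait beta-pattern similarity.

    Returns a dict with ``factors``, ``loadings``, ``results``,
    ``similarity``, ``winsor_pct`` and a formatted ``report`` string.
    Refuses to model fewer than 10 participants.
    """
    if config is None:
        config = PipelineConfig()
    n_participants = summary["participant"].nunique()
    if n_participants < 10:
        raise ValueError(
            f"only {n_participants} participants: need at least 10 to fit models"
        )
    factors, factor_results = trait_factors.build_factors(traits)
    loadings = trait_factors.validate_loadings(factors, traits)
    matrix, winsor_pct = association_stats.winsorize_and_standardize(
        summary, sd_limit=config.winsor_sd
    )
    results = association_stats.fit_all(
        matrix, factors, alpha=config.alpha, include_topic_vc=config.include_topic_vc
    )
    similarity = association_stats.pattern_similarity_table(results)
    report = format_report(results, similarity, factor_results, config)
    return {
        "factors": factors,
        "factor_results": factor_results,
        "loadings": loadings,
        "results": results,
        "similarity": similarity,
        "winsor_pct": winsor_pct,
        "report": report,
    }


def format_report(
    results: pd.DataFrame,
    similarity: pd.DataFrame,
    factor_results: dict,
    config: PipelineConfig,
) -> str:
    """Human-readable table of standardized betas with CIs per trait and
    measure, plus the pairwise beta-pattern correlations."""
    lines = ["Trait-behavior associations (standardized beta [95% CI])", ""]
    header = f"{'measure':<18}" + "".join(f"{t:>26}" for t in TRAIT_NAMES)
    lines.append(header)
    for measure in MEASURES:
        sub = results[results.measure == measure]
        if sub.empty:
            continue
        cells = []
        for t in TRAIT_NAMES:
            row = sub[sub.trait == t]
            if row.empty:
                cells.append(f"{'--':>26}")
                continue
            r = row.iloc[0]
            star = "*" if r.p_adj <= config.alpha else (
                "." if r.p <= config.alpha else " "
            )
            cells.append(
                f"{r.beta:+.2f} [{r.ci_low:+.2f},{r.ci_high:+.2f}]{star}".rjust(26)
            )
        lines.append(f"{measure:<18}" + "".join(cells))
    lines.append("")
    lines.append(f"('.' p<= {config.alpha} uncorrected, '*' FDR-significant; "
                 f"family = {len(results)} tests)")
    lines.append("")
    lines.append("Cross-trait behavior-pattern similarity (Pearson r over betas)")
    for _, row in similarity.iterrows():
        lines.append(
            f"  {row.trait_a} vs {row.trait_b}: r={row.r:+.2f} "
            f"[{row.ci_low:+.2f},{row.ci_high:+.2f}], t({row.df})={row.t:+.2f}, "
            f"p={row.p:.3g} (over {row.n_measures} measures)"
        )
    lines.append("")
    for g, res in factor_results.items():
        lines.append(
            f"factor {g}: first component explains "
            f"{100 * res.explained_variance:.1f}% of its {len(res.loadings)} scales"
        )
    return "\n".join(lines)
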