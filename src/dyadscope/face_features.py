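"""Smile intensity from mouth-corner action-unit activations.

The headset's face tracker reports the activation (0-100) of the left
and right mouth-corner action units; the per-sample smile score is
their arithmetic mean and the session summary is the mean score over
the whole conversation period (smiling and neutral frames alike).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["smile_intensity", "load_face_csv"]


def load_face_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def smile_intensity(
    au_left: np.ndarray, au_right: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample smile score ``(au_left + au_right) / 2`` and its mean
    over all samples."""
    au_left = np.asarray(au_left, dtype=float)
    au_right = np.asarray(au_right, dtype=float)
    if au_left.size == 0 or au_right.size == 0:
        raise ValueError("empty action-unit stream")
    if au_left.shape != au_right.shape:
        raise ValueError("left/right action-unit streams differ in length")
    for side, arr in (("left", au_left), ("right", au_right)):
        if np.any(arr < 0) or np.any(arr > 100):
            raise ValueError(f"au_{side} values must lie in [0, 100]")
    score = 0.5 * (au_left + au_right)
    return score, float(score.mean())
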