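"""Gaze preprocessing and at-eyes classification.

The pipeline masks eye-tracking samples recorded during blinks (plus a
100 ms guard on each side), fills the masked spans with shape-preserving
piecewise cubic Hermite interpolation, low-pass filters the ray
components with a zero-phase second-order Butterworth response
(10 Hz cutoff), and classifies each sample as directed at the partner's
eye region when any of the left, right, or cyclopean (combined) gaze
rays passes within 2 degrees of visual angle of either of the partner's
eye centers. At-eyes fractions are summarized separately for the
participant's own speaking and listening phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "GazeStream",
    "EyeTargets",
    "GazeSummary",
    "mask_blinks",
    "interpolate_gaps",
    "smooth",
    "angle_to_target",
    "classify_at_eyes",
    "summarize_by_phase",
    "preprocess",
    "load_gaze_csv",
    "load_targets_csv",
]


@dataclass
class GazeStream:
    """Binocular gaze rays sampled at a nominally uniform rate.

    ``origin_*`` are 3-D eye positions (scene units), ``dir_*`` unit
    direction vectors, ``blink`` per-sample blink flags and ``valid``
    the post-masking validity mask (all True before masking).
    """

    t: np.ndarray
    origin_l: np.ndarray
    dir_l: np.ndarray
    origin_r: np.ndarray
    dir_r: np.ndarray
    blink: np.ndarray
    valid: np.ndarray | None = None
    data_loss_pct: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size == 0:
            raise ValueError("empty gaze stream")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("dir_l", "dir_r"):
            d = np.asarray(getattr(self, name), dtype=float)
            norms = np.linalg.norm(d, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError(f"{name} contains zero-length directions")
            setattr(self, name, d / norms)
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)

    @property
    def fs(self) -> float:
        if self.t.size < 2:
            return float("inf")
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class EyeTargets:
    """Time-varying positions of the partner's eye centers."""

    t: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("eye-target coordinates must be finite")


@dataclass
class GazeSummary:
    pct_at_eyes_speaking: float
    pct_at_eyes_listening: float
    data_loss_pct: float
    usable: bool = True


def load_gaze_csv(path) -> GazeStream:
    df = pd.read_csv(path)
    return GazeStream(
        t=df["t_s"].to_numpy(),
        origin_l=df[["lx", "ly", "lz"]].to_numpy(),
        dir_l=df[["ldx", "ldy", "ldz"]].to_numpy(),
        origin_r=df[["rx", "ry", "rz"]].to_numpy(),
        dir_r=df[["rdx", "rdy", "rdz"]].to_numpy(),
        blink=df["blink"].to_numpy().astype(bool),
    )


def load_targets_csv(path) -> EyeTargets:
    df = pd.read_csv(path)
    return EyeTargets(
        t=df["t_s"].to_numpy(),
        left=df[["left_x", "left_y", "left_z"]].to_numpy(),
        right=df[["right_x", "right_y", "right_z"]].to_numpy(),
    )


def mask_blinks(stream: GazeStream, pad_ms: float = 100.0) -> GazeStream:
    """Mark samples invalid during blinks and within ``pad_ms`` of any
    blink sample; record the masked fraction as ``data_loss_pct``."""
    if pad_ms < 0:
        raise ValueError("pad_ms must be >= 0")
    t = stream.t
    blink = np.asarray(stream.blink, dtype=bool)
    invalid = blink.copy()
    if blink.any():
        pad = pad_ms / 1000.0
        bt = t[blink]
        # a sample is masked if within pad of any blink sample
        idx = np.searchsorted(bt, t)
        left = np.clip(idx - 1, 0, bt.size - 1)
        right = np.clip(idx, 0, bt.size - 1)
        near = np.minimum(np.abs(t - bt[left]), np.abs(t - bt[right]))
        invalid |= near <= pad + 1e-9
    out = replace(stream)
    out.valid = ~invalid
    out.data_loss_pct = 100.0 * invalid.mean()
    return out


def interpolate_gaps(stream: GazeStream) -> GazeStream:
    """Fill invalid spans of every ray component with piecewise cubic
    Hermite (shape-preserving) interpolation; directions are
    renormalized afterwards. Leading/trailing invalid spans are held at
    the nearest valid value."""
    valid = stream.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid samples to interpolate")
    if valid.all():
        return replace(stream)
    t, tv = stream.t, stream.t[valid]
    out = replace(stream)

    def fill(arr: np.ndarray) -> np.ndarray:
        res = arr.astype(float).copy()
        for c in range(arr.shape[1]):
            interp = PchipInterpolator(tv, arr[valid, c], extrapolate=False)
            col = interp(t)
            col[t < tv[0]] = arr[valid, c][0]
            col[t > tv[-1]] = arr[valid, c][-1]
            res[:, c] = np.where(valid, arr[:, c], col)
        return res

    out.origin_l = fill(stream.origin_l)
    out.origin_r = fill(stream.origin_r)
    dl = fill(stream.dir_l)
    dr = fill(stream.dir_r)
    out.dir_l = dl / np.linalg.norm(dl, axis=1, keepdims=True)
    out.dir_r = dr / np.linalg.norm(dr, axis=1, keepdims=True)
    return out


def smooth(stream: GazeStream, cutoff_hz: float = 10.0, order: int = 2) -> GazeStream:
    """Zero-phase (forward-backward) Butterworth low-pass of every ray
    component; directions renormalized."""
    fs = stream.fs
    if cutoff_hz >= fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {fs / 2:.3g} Hz"
        )
    sos = butter(order, cutoff_hz, fs=fs, output="sos")

    def lp(arr: np.ndarray) -> np.ndarray:
        return sosfiltfilt(sos, arr, axis=0)

    out = replace(stream)
    out.origin_l = lp(stream.origin_l)
    out.origin_r = lp(stream.origin_r)
    dl = lp(stream.dir_l)
    dr = lp(stream.dir_r)
    out.dir_l = dl / np.linalg.norm(dl, axis=1, keepdims=True)
    out.dir_r = dr / np.linalg.norm(dr, axis=1, keepdims=True)
    return out


def preprocess(
    stream: GazeStream,
    pad_ms: float = 100.0,
    cutoff_hz: float = 10.0,
    order: int = 2,
) -> GazeStream:
    """Blink masking -> Hermite interpolation -> zero-phase smoothing."""
    masked = mask_blinks(stream, pad_ms)
    if masked.valid.sum() < 2:
        # fully (or almost fully) lost stream; flagged downstream
        masked.data_loss_pct = 100.0 * (~masked.valid).mean()
        return masked
    return smooth(interpolate_gaps(masked), cutoff_hz=cutoff_hz, order=order)


def angle_to_target(
    origin: np.ndarray, direction: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Angle in degrees between gaze direction(s) and the ray from the
    eye origin to the target point, in [0, 180]."""
    origin = np.atleast_2d(np.asarray(origin, dtype=float))
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    v = target - origin
    nv = np.linalg.norm(v, axis=-1)
    nd = np.linalg.norm(direction, axis=-1)
    if np.any(nv == 0):
        raise ValueError("target coincides with the eye origin")
    if np.any(nd == 0):
        raise ValueError("zero-length gaze direction")
    cosang = np.sum(direction * v, axis=-1) / (nd * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang if ang.size > 1 else float(ang[0])


def classify_at_eyes(
    stream: GazeStream,
    targets: EyeTargets,
    threshold_deg: float = 2.0,
    time_tolerance: float | None = None,
) -> np.ndarray:
    """Per-sample at-eyes classification.

    A sample is at-eyes iff the minimum over {left ray, right ray,
    cyclopean ray} x {partner left eye, partner right eye} of the
    visual angle is <= ``threshold_deg`` (inclusive). The cyclopean ray
    originates at the midpoint of the eye origins with direction equal
    to the normalized mean of the two eye directions. Targets sampled
    on a different time base are aligned by nearest neighbor within
    half a sample period.
    """
    t = stream.t
    if time_tolerance is None:
        time_tolerance = 0.5 / stream.fs
    if targets.t.size == t.size and np.allclose(targets.t, t, atol=1e-9):
        tl, tr = targets.left, targets.right
    else:
        idx = np.clip(np.searchsorted(targets.t, t), 1, targets.t.size - 1)
        idx = idx - (np.abs(targets.t[idx - 1] - t) <= np.abs(targets.t[idx] - t))
        if np.any(np.abs(targets.t[idx] - t) > time_tolerance + 1e-12):
            raise ValueError("gaze and target time bases are misaligned")
        tl, tr = targets.left[idx], targets.right[idx]

    origin_c = 0.5 * (stream.origin_l + stream.origin_r)
    dir_c = stream.dir_l + stream.dir_r
    dir_c = dir_c / np.linalg.norm(dir_c, axis=1, keepdims=True)

    angles = [
        angle_to_target(o, d, g)
        for o, d in (
            (stream.origin_l, stream.dir_l),
            (stream.origin_r, stream.dir_r),
            (origin_c, dir_c),
        )
        for g in (tl, tr)
    ]
    min_angle = np.min(np.column_stack([np.atleast_1d(a) for a in angles]), axis=1)
    return min_angle <= threshold_deg


def summarize_by_phase(
    at_eyes: np.ndarray,
    speaking: np.ndarray,
    listening: np.ndarray,
    data_loss_pct: float = 0.0,
    include_mask: np.ndarray | None = None,
) -> GazeSummary:
    """At-eyes percentage during own speaking and own listening phases.

    Samples in neither phase (overlap, mutual silence) enter no
    denominator. ``include_mask`` optionally restricts the tally (e.g.
    to exclude interpolated samples); by default all samples count. A
    phase with zero samples yields NaN and flags the summary unusable.
    """
    at_eyes = np.asarray(at_eyes, dtype=bool)
    if include_mask is None:
        include_mask = np.ones_like(at_eyes)
    sp = np.asarray(speaking, dtype=bool) & include_mask
    li = np.asarray(listening, dtype=bool) & include_mask

    def pct(mask: np.ndarray) -> float:
        return 100.0 * at_eyes[mask].mean() if mask.any() else float("nan")

    p_sp, p_li = pct(sp), pct(li)
    usable = sp.any() and li.any() and data_loss_pct < 100.0
    return GazeSummary(p_sp, p_li, data_loss_pct, usable=bool(usable))
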