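"""Cardiac markers: R-peak detection, RR cleaning, heart rate, HF-HRV.

QRS complexes are detected with the two-event-related-moving-averages
method: the ECG is band-pass filtered to 8-20 Hz (third-order
Butterworth), squared, and two moving averages — one at the QRS time
scale (120 ms) and one at the beat time scale (600 ms) — are compared;
stretches where the QRS-scale average exceeds the beat-scale average
plus a small offset, and that are at least one QRS window long, are
blocks of interest, each contributing the time of its squared-signal
maximum as a beat.

RR intervals (ms) outside [300, 2000] ms or deviating more than 30%
from the previous accepted interval are treated as artifacts and
replaced by interpolation between accepted neighbors — an automated
surrogate for visual inspection.

Heart rate is 60 divided by the mean RR interval in seconds. HF-HRV is
the natural log of the power (ms^2) of the equidistantly resampled RR
series (cubic spline over beat times, then bandlimited resampling to
4 Hz) in the 0.15-0.4 Hz band, estimated with Welch's method using
30 s Hann windows at 50% overlap; the one-sided density is normalized
so its integral over frequency equals the variance of the
mean-detrended series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, resample, sosfiltfilt, welch

__all__ = [
    "RRSeries",
    "CardiacSummary",
    "detect_qrs",
    "clean_rr",
    "heart_rate",
    "equidistant_rr",
    "hf_hrv",
    "summarize_cardiac",
    "QRS_WINDOW_S",
    "BEAT_WINDOW_S",
]

# two-moving-averages detector constants (published defaults)
QRS_WINDOW_S = 0.120
BEAT_WINDOW_S = 0.600
THRESHOLD_OFFSET_BETA = 0.08
BANDPASS_HZ = (8.0, 20.0)


@dataclass
class RRSeries:
    """Interbeat-interval series: beat times (s), RR intervals (ms) and
    artifact-correction bookkeeping."""

    beat_times: np.ndarray
    rr_ms: np.ndarray
    n_corrected: int = 0
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class CardiacSummary:
    heart_rate_bpm: float
    hf_hrv: float
    n_corrected: int = 0
    low_quality: bool = False


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_qrs(t: np.ndarray, mv: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Detect R-peak times (s) from an ECG trace.

    Requires at least 10 s of signal. A flat (zero-variance) trace
    yields an empty array.
    """
    t = np.asarray(t, dtype=float)
    mv = np.asarray(mv, dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    if t[-1] - t[0] < 10.0:
        raise ValueError("need at least 10 s of ECG signal")
    if np.ptp(mv) == 0:
        return np.empty(0)

    sos = butter(3, BANDPASS_HZ, btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, mv) ** 2

    w_qrs = int(round(QRS_WINDOW_S * fs))
    w_beat = int(round(BEAT_WINDOW_S * fs))
    ma_qrs = _moving_average(y, w_qrs)
    ma_beat = _moving_average(y, w_beat)
    thr = ma_beat + THRESHOLD_OFFSET_BETA * float(np.mean(y))

    block = ma_qrs > thr
    d = np.diff(np.concatenate([[0], block.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    beats = []
    for a, b in zip(starts, ends):
        if b - a >= w_qrs:  # reject blocks narrower than one QRS window
            beats.append(t[a + int(np.argmax(y[a:b]))])
    return np.asarray(beats)


def clean_rr(beat_times: np.ndarray, max_quality_fraction: float = 0.2) -> RRSeries:
    """Build an artifact-corrected RR series from beat times.

    Intervals outside [300, 2000] ms or differing by more than 30% from
    the previous accepted interval are flagged and replaced by linear
    interpolation between accepted neighbors. If more than
    ``max_quality_fraction`` of intervals needed correction, the series
    is marked low-quality.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise ValueError("need at least 2 beats")
    rr = np.diff(beat_times) * 1000.0
    flagged = np.zeros(rr.size, dtype=bool)
    prev_accepted = None
    for i, v in enumerate(rr):
        bad = not (300.0 <= v <= 2000.0)
        if not bad and prev_accepted is not None:
            bad = abs(v - prev_accepted) > 0.30 * prev_accepted
        flagged[i] = bad
        if not bad:
            prev_accepted = v
    if flagged.any():
        good = np.flatnonzero(~flagged)
        if good.size == 0:
            raise ValueError("no acceptable RR intervals")
        idx = np.flatnonzero(flagged)
        rr = rr.copy()
        rr[idx] = np.interp(idx, good, rr[good])
    return RRSeries(
        beat_times=beat_times,
        rr_ms=rr,
        n_corrected=int(flagged.sum()),
        low_quality=bool(flagged.mean() > max_quality_fraction),
    )


def heart_rate(rr: RRSeries) -> float:
    """Heart rate in bpm: 60 / mean RR interval (s)."""
    return 60.0 / float(np.mean(rr.rr_ms) / 1000.0)


def equidistant_rr(
    rr: RRSeries, fs_out: float = 4.0, fs_fine: float = 32.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the RR series onto a uniform grid.

    The irregular series (RR value attributed to the closing beat of
    each interval) is first interpolated with a cubic spline onto a
    fine uniform grid, then bandlimited (Fourier) resampled down to
    ``fs_out``. Returns ``(t, rr_ms)``.
    """
    tk = rr.beat_times[1:]
    if tk.size < 4:
        raise ValueError("too few beats for spline resampling")
    spline = CubicSpline(tk, rr.rr_ms)
    t_fine = np.arange(tk[0], tk[-1], 1.0 / fs_fine)
    x_fine = spline(t_fine)
    n_out = int(round(t_fine.size * fs_out / fs_fine))
    x_out = resample(x_fine, n_out)
    t_out = tk[0] + np.arange(n_out) / fs_out
    return t_out, x_out


def _band_integral(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of a piecewise-linear PSD over [lo, hi],
    interpolating the band edges."""
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    if hi <= lo:
        return 0.0
    inner = f[(f > lo) & (f < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, f, psd)
    return float(np.trapezoid(vals, grid))


def hf_hrv(
    rr: RRSeries,
    band_hz: tuple[float, float] = (0.15, 0.40),
    window_s: float = 30.0,
    overlap: float = 0.5,
    fs_out: float = 4.0,
) -> float:
    """Natural log of the HF-band power (ms^2) of the RR series.

    Requires at least two Welch windows (60 s at the defaults). Zero
    band power is guarded and returned as ``-inf``.
    """
    if rr.duration_s < 2.0 * window_s:
        raise ValueError(
            f"need at least {2 * window_s:.0f} s of RR data for the Welch estimate"
        )
    _, x = equidistant_rr(rr, fs_out=fs_out)
    x = x - x.mean()
    nperseg = int(round(window_s * fs_out))
    f, psd = welch(
        x,
        fs=fs_out,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
        scaling="density",
    )
    power = _band_integral(f, psd, *band_hz)
    if power <= 0:
        return float("-inf")
    return math.log(power)


def summarize_cardiac(
    beat_times: np.ndarray,
    t_range: tuple[float, float] | None = None,
    min_duration_s: float = 60.0,
) -> CardiacSummary:
    """Heart rate and HF-HRV from beat times, optionally restricted to
    a half-open time window (e.g. one conversation topic)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if t_range is not None:
        lo, hi = t_range
        beat_times = beat_times[(beat_times >= lo) & (beat_times < hi)]
    if beat_times.size < 2:
        return CardiacSummary(float("nan"), float("nan"), low_quality=True)
    rr = clean_rr(beat_times)
    hr = heart_rate(rr)
    if rr.duration_s >= min_duration_s:
        hf = hf_hrv(rr)
    else:
        hf = float("nan")
    return CardiacSummary(hr, hf, rr.n_corrected, rr.low_quality)


def load_rr_csv(path) -> np.ndarray:
    return pd.read_csv(path)["r_peak_time_s"].to_numpy()


def load_ecg_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["t_s"].to_numpy(), df["mv"].to_numpy()
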