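"""Blink masking, interpolation, smoothing, and at-eyes geometry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dyadscope import gaze_features as gf

FS = 50.0


def make_stream(n=200, blink_idx=(), dir_l=None, dir_r=None, origin=None):
    t = np.arange(n) / FS
    if origin is None:
        origin = np.tile([0.0, 1.5, 0.0], (n, 1))
    if dir_l is None:
        dir_l = np.tile([0.0, 0.0, 1.0], (n, 1))
    if dir_r is None:
        dir_r = dir_l.copy()
    blink = np.zeros(n, dtype=bool)
    blink[list(blink_idx)] = True
    return gf.GazeStream(
        t=t,
        origin_l=origin - [0.03, 0, 0],
        dir_l=dir_l,
        origin_r=origin + [0.03, 0, 0],
        dir_r=dir_r,
        blink=blink,
    )


class TestMaskBlinks:
    def test_no_blinks_masks_nothing(self):
        s = gf.mask_blinks(make_stream())
        assert s.valid.all()
        assert s.data_loss_pct == 0.0

    def test_single_blink_masks_eleven_samples_at_50hz(self):
        s = gf.mask_blinks(make_stream(blink_idx=[100]), pad_ms=100)
        # brute-force window check: every sample within 100 ms
        t = s.t
        expected = np.abs(t - t[100]) <= 0.1 + 1e-9
        assert np.array_equal(~s.valid, expected)
        assert (~s.valid).sum() == 11

    def test_all_blink_is_total_loss(self):
        s = gf.mask_blinks(make_stream(n=50, blink_idx=range(50)))
        assert s.data_loss_pct == 100.0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            make_stream(n=0)


class TestInterpolateGaps:
    def test_identity_without_gaps(self):
        s = gf.mask_blinks(make_stream())
        out = gf.interpolate_gaps(s)
        assert np.allclose(out.origin_l, s.origin_l)
        assert np.allclose(out.dir_l, s.dir_l)

    def test_linear_ramp_filled_exactly(self):
        n = 100
        origin = np.column_stack(
            [np.linspace(0, 1, n), np.full(n, 1.5), np.zeros(n)]
        )
        s = make_stream(n=n, blink_idx=range(40, 50), origin=origin)
        out = gf.interpolate_gaps(gf.mask_blinks(s, pad_ms=0))
        assert np.allclose(out.origin_l[:, 0], origin[:, 0] - 0.03, atol=1e-12)

    def test_directions_unit_norm_after_fill(self):
        n = 100
        ang = np.linspace(0, 0.3, n)
        dirs = np.column_stack([np.sin(ang), np.zeros(n), np.cos(ang)])
        s = make_stream(n=n, blink_idx=range(40, 55), dir_l=dirs, dir_r=dirs)
        out = gf.interpolate_gaps(gf.mask_blinks(s, pad_ms=0))
        assert np.allclose(np.linalg.norm(out.dir_l, axis=1), 1.0, atol=1e-9)

    def test_too_few_valid_samples_rejected(self):
        s = make_stream(n=20, blink_idx=range(1, 20))
        with pytest.raises(ValueError):
            gf.interpolate_gaps(gf.mask_blinks(s, pad_ms=0))


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_interpolation_never_overshoots_monotone_data(seed):
    """Shape preservation: over a gap in monotone data the interpolant
    stays within the bracketing knot values."""
    rng = np.random.default_rng(seed)
    n = 80
    vals = np.cumsum(rng.uniform(0.0, 0.1, n)) + 1.0
    origin = np.column_stack([vals, np.full(n, 1.5), np.zeros(n)])
    a, b = sorted(rng.choice(np.arange(5, n - 5), 2, replace=False))
    if a == b:
        b += 1
    s = make_stream(n=n, blink_idx=range(a, b), origin=origin)
    out = gf.interpolate_gaps(gf.mask_blinks(s, pad_ms=0))
    filled = out.origin_l[a:b, 0]
    lo, hi = origin[a - 1, 0] - 0.03, origin[b, 0] - 0.03
    assert np.all(filled >= lo - 1e-9) and np.all(filled <= hi + 1e-9)


class TestSmooth:
    def test_constant_signal_unchanged(self):
        s = make_stream()
        out = gf.smooth(s)
        assert np.allclose(out.origin_l, s.origin_l, atol=1e-9)
        assert np.allclose(out.dir_l, s.dir_l, atol=1e-9)

    @pytest.mark.parametrize(
        "freq,check",
        [
            (1.0, lambda att: att < 0.01),  # passband: < 1% attenuation
            (20.0, lambda att: att > 0.90),  # stopband: > 90% attenuation
        ],
    )
    def test_butterworth_attenuation(self, freq, check):
        n = 1000
        t = np.arange(n) / FS
        wob = 0.02 * np.sin(2 * np.pi * freq * t)
        origin = np.column_stack([wob, np.full(n, 1.5), np.zeros(n)])
        s = make_stream(n=n, origin=origin)
        out = gf.smooth(s, cutoff_hz=10, order=2)
        x = out.origin_l[200:-200, 0] + 0.03
        att = 1.0 - np.max(np.abs(x)) / 0.02
        assert check(att)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gf.smooth(make_stream(), cutoff_hz=25.0)


class TestAngleToTarget:
    def test_toward_and_opposite(self):
        o = np.array([0.0, 0.0, 0.0])
        tgt = np.array([0.0, 0.0, 2.0])
        assert gf.angle_to_target(o, np.array([0, 0, 1.0]), tgt) == pytest.approx(0.0)
        assert gf.angle_to_target(o, np.array([0, 0, -1.0]), tgt) == pytest.approx(
            180.0
        )

    def test_matches_acos_oracle_on_random_configurations(self, rng):
        for _ in range(1000):
            o = rng.normal(size=3)
            d = rng.normal(size=3)
            tgt = rng.normal(size=3)
            if np.linalg.norm(tgt - o) < 1e-6 or np.linalg.norm(d) < 1e-6:
                continue
            v = tgt - o
            expected = np.degrees(
                np.arccos(
                    np.clip(
                        np.dot(d, v) / (np.linalg.norm(d) * np.linalg.norm(v)), -1, 1
                    )
                )
            )
            assert gf.angle_to_target(o, d, tgt) == pytest.approx(expected, abs=1e-9)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            gf.angle_to_target(
                np.zeros(3), np.zeros(3), np.array([0, 0, 1.0])
            )


def offset_dir(to_target: np.ndarray, deg: float) -> np.ndarray:
    axis = np.cross(to_target, [0.0, 1.0, 0.0])
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(deg) * axis).apply(to_target)


class TestClassifyAtEyes:
    def make(self, left_off, right_off, n=1):
        t = np.arange(n) / FS
        tgt = np.array([0.0, 1.5, 1.0])
        targets = gf.EyeTargets(
            t=t,
            left=np.tile(tgt + [-0.032, 0, 0], (n, 1)),
            right=np.tile(tgt + [0.032, 0, 0], (n, 1)),
        )
        ol = np.tile([-0.03, 1.5, 0.0], (n, 1))
        orr = np.tile([0.03, 1.5, 0.0], (n, 1))
        dl = np.tile(
            offset_dir((tgt + [-0.032, 0, 0]) - ol[0], left_off), (n, 1)
        )
        dr = np.tile(
            offset_dir((tgt + [-0.032, 0, 0]) - orr[0], right_off), (n, 1)
        )
        stream = gf.GazeStream(
            t=t, origin_l=ol, dir_l=dl, origin_r=orr, dir_r=dr,
            blink=np.zeros(n, dtype=bool),
        )
        return stream, targets

    def test_both_on_target(self):
        s, tg = self.make(0.0, 0.0)
        assert gf.classify_at_eyes(s, tg).all()

    def test_all_angles_beyond_threshold(self):
        s, tg = self.make(15.0, 17.0)
        assert not gf.classify_at_eyes(s, tg).any()

    def test_or_rule_one_eye_suffices(self):
        # left eye 5 degrees off, right eye 1.5 degrees off -> at eyes
        s, tg = self.make(5.0, 1.5)
        assert gf.classify_at_eyes(s, tg).all()

    def test_inclusive_at_exact_threshold(self):
        s, tg = self.make(8.0, 8.0)
        ang = gf.angle_to_target(s.origin_l[0], s.dir_l[0], tg.left[0])
        cyc_o = 0.5 * (s.origin_l + s.origin_r)
        cyc_d = s.dir_l + s.dir_r
        angles = [
            gf.angle_to_target(o, d, g)
            for o, d in (
                (s.origin_l[0], s.dir_l[0]),
                (s.origin_r[0], s.dir_r[0]),
                (cyc_o[0], cyc_d[0]),
            )
            for g in (tg.left[0], tg.right[0])
        ]
        thr = min(angles)
        assert gf.classify_at_eyes(s, tg, threshold_deg=thr).all()
        assert not gf.classify_at_eyes(s, tg, threshold_deg=thr - 1e-9).any()

    def test_rigid_motion_invariance(self, rng):
        s, tg = self.make(1.0, 4.0, n=20)
        base = gf.classify_at_eyes(s, tg)
        R = Rotation.random(rng=np.random.default_rng(3)).as_matrix()
        shift = np.array([0.5, -2.0, 3.0])

        def move(x):
            return x @ R.T + shift

        s2 = gf.GazeStream(
            t=s.t,
            origin_l=move(s.origin_l),
            dir_l=s.dir_l @ R.T,
            origin_r=move(s.origin_r),
            dir_r=s.dir_r @ R.T,
            blink=s.blink,
        )
        tg2 = gf.EyeTargets(t=tg.t, left=move(tg.left), right=move(tg.right))
        assert np.array_equal(gf.classify_at_eyes(s2, tg2), base)

    def test_misaligned_time_base_rejected(self):
        s, tg = self.make(0.0, 0.0, n=10)
        tg_bad = gf.EyeTargets(t=tg.t + 0.5, left=tg.left, right=tg.right)
        with pytest.raises(ValueError):
            gf.classify_at_eyes(s, tg_bad)


class TestSummarizeByPhase:
    def test_all_at_eyes(self):
        n = 100
        at = np.ones(n, dtype=bool)
        sp = np.zeros(n, dtype=bool)
        sp[:40] = True
        li = ~sp
        s = gf.summarize_by_phase(at, sp, li)
        assert s.pct_at_eyes_speaking == 100.0
        assert s.pct_at_eyes_listening == 100.0

    def test_at_eyes_only_while_speaking(self):
        n = 100
        sp = np.zeros(n, dtype=bool)
        sp[:40] = True
        li = np.zeros(n, dtype=bool)
        li[40:80] = True  # remaining 20 samples in neither phase
        s = gf.summarize_by_phase(sp.copy(), sp, li)
        assert s.pct_at_eyes_speaking == 100.0
        assert s.pct_at_eyes_listening == 0.0

    def test_matches_per_sample_tally(self, rng):
        n = 500
        at = rng.random(n) < 0.3
        ph = rng.integers(0, 3, n)  # 0 speak, 1 listen, 2 neither
        s = gf.summarize_by_phase(at, ph == 0, ph == 1)
        want_sp = 100.0 * sum(at[i] for i in range(n) if ph[i] == 0) / (ph == 0).sum()
        want_li = 100.0 * sum(at[i] for i in range(n) if ph[i] == 1) / (ph == 1).sum()
        assert s.pct_at_eyes_speaking == pytest.approx(want_sp)
        assert s.pct_at_eyes_listening == pytest.approx(want_li)

    def test_zero_phase_samples_flagged(self):
        n = 10
        s = gf.summarize_by_phase(
            np.ones(n, dtype=bool), np.ones(n, dtype=bool), np.zeros(n, dtype=bool)
        )
        assert np.isnan(s.pct_at_eyes_listening)
        assert not s.usable
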