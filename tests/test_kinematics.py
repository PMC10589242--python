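"""Speed computation, event detection, and per-trial kinematic measures."""

import numpy as np
import pytest

from graspsupp import (
    FilterSpec,
    InvalidMeasureError,
    MarkerTimeSeries,
    TrialEvents,
    compute_speed,
    detect_contact,
    detect_lift_onset,
    digit_separation,
    loading_time,
    object_roll,
)
from graspsupp.kinematics import EventTime
from graspsupp.synthdata import minimum_jerk_position

FS = 100.0


def make_series(n=200, **markers):
    t = np.arange(n) / FS
    default = np.zeros((n, 3))
    pos = {m: default.copy() for m in ("thumb", "index", "obj1", "obj2", "obj3")}
    for k, v in markers.items():
        pos[k] = v
    return MarkerTimeSeries(t=t, positions=pos, fs=FS)


class TestComputeSpeed:
    def test_stationary_markers_zero_speed(self):
        s = make_series()
        speed = compute_speed(s, ("thumb", "index"))
        assert np.allclose(speed, 0.0, atol=1e-9)

    def test_uniform_motion_steady_state(self):
        n = 300
        pos = np.zeros((n, 3))
        pos[:, 0] = 20.0 * np.arange(n) / FS  # 20 cm/s along x
        s = make_series(n=n, thumb=pos, index=pos)
        speed = compute_speed(s, ("thumb", "index"))
        assert np.allclose(speed[50:-50], 20.0, rtol=1e-6)

    def test_minimum_jerk_peak_speed_matches_closed_form(self):
        n, D, T = 200, 30.0, 1.0
        t = np.arange(n) / FS
        pos = np.zeros((n, 3))
        pos[:, 1] = D * minimum_jerk_position(t / T)
        s = make_series(n=n, thumb=pos, index=pos)
        speed = compute_speed(s, ("thumb", "index"))
        assert speed.max() == pytest.approx(1.875 * D / T, rel=0.02)

    def test_missing_marker_raises(self):
        s = make_series()
        with pytest.raises(ValueError, match="not present"):
            compute_speed(s, ("thumb", "nose"))

    def test_filter_is_zero_phase(self):
        # time-reversal symmetry holds away from the boundary transients
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(size=500))
        f = FilterSpec()
        forward = f.apply(x, FS)
        reversed_ = f.apply(x[::-1], FS)[::-1]
        assert np.allclose(forward[50:-50], reversed_[50:-50], atol=1e-3)
        # and a smooth pulse is not delayed
        pulse = np.exp(-0.5 * ((np.arange(500) - 250) / 20.0) ** 2)
        assert abs(int(np.argmax(f.apply(pulse, FS))) - 250) <= 1

    def test_absolute_hz_mode_equivalent_normalized(self):
        x = np.sin(np.linspace(0, 20, 400))
        a = FilterSpec(cutoff=0.3, mode="fraction_nyquist").apply(x, FS)
        b = FilterSpec(cutoff=15.0, mode="hz").apply(x, FS)
        assert np.allclose(a, b)


class TestEventDetection:
    def test_no_lift_when_object_static(self):
        t = np.arange(100) / FS
        res = detect_lift_onset(np.zeros(100), t)
        assert not res.valid
        assert "no lift" in res.reason

    def test_lift_at_step(self):
        t = np.arange(100) / FS
        speed = np.zeros(100)
        speed[40:] = 15.0
        res = detect_lift_onset(speed, t)
        assert res.valid
        assert res.index == 40
        assert res.time_s == pytest.approx(t[40])

    def test_threshold_is_strict(self):
        t = np.arange(10) / FS
        res = detect_lift_onset(np.full(10, 10.0), t)  # exactly at threshold: no event
        assert not res.valid

    def test_contact_with_still_hand_is_last_sample_before_lift(self):
        t = np.arange(100) / FS
        lift = EventTime(t[60], 60, True)
        res = detect_contact(np.zeros(100), t, lift)
        assert res.valid
        assert res.index == 59

    def test_contact_is_last_downward_crossing(self):
        t = np.arange(100) / FS
        hand = np.concatenate([np.full(30, 50.0), np.zeros(70)])  # transport ends at 30
        lift = EventTime(t[60], 60, True)
        res = detect_contact(hand, t, lift)
        assert res.index == 30

    def test_fast_hand_never_contacts(self):
        t = np.arange(100) / FS
        lift = EventTime(t[60], 60, True)
        res = detect_contact(np.full(100, 50.0), t, lift)
        assert not res.valid

    def test_invalid_lift_propagates(self):
        t = np.arange(100) / FS
        res = detect_contact(np.zeros(100), t, EventTime(np.nan, -1, False, "no lift"))
        assert not res.valid


class TestMeasures:
    def test_constant_separation(self):
        thumb = np.zeros((200, 3))
        thumb[:, 2] = 2.0
        s = make_series(thumb=thumb)
        contact = EventTime(0.5, 50, True)
        assert digit_separation(s, contact) == pytest.approx(2.0)

    def test_separation_antisymmetric_under_digit_swap(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3))
        s1 = make_series(thumb=a, index=b)
        s2 = make_series(thumb=b, index=a)
        contact = EventTime(0.5, 50, True)
        assert digit_separation(s1, contact) == pytest.approx(-digit_separation(s2, contact))

    def test_instantaneous_window(self):
        thumb = np.zeros((200, 3))
        thumb[:, 2] = np.linspace(0, 1, 200)
        s = make_series(thumb=thumb)
        contact = EventTime(0.5, 50, True)
        assert digit_separation(s, contact, window_ms=0) == pytest.approx(thumb[50, 2])

    def test_truncated_window_invalid(self):
        s = make_series(n=60)
        contact = EventTime(0.59, 59, True)
        with pytest.raises(InvalidMeasureError):
            digit_separation(s, contact, window_ms=100)

    def test_loading_time_arithmetic(self):
        assert loading_time(TrialEvents(1.0, 1.25, True)) == pytest.approx(250.0)
        assert loading_time(TrialEvents(1.0, 1.0, True)) == 0.0
        with pytest.raises(InvalidMeasureError):
            loading_time(TrialEvents(np.nan, np.nan, False, "bad"))

    def test_static_object_has_zero_roll(self):
        obj = np.tile(np.array([[-5.0, 0, 0]]), (200, 1))
        obj3 = np.tile(np.array([[5.0, 0, 0]]), (200, 1))
        s = make_series(obj1=obj, obj3=obj3)
        lift = EventTime(0.5, 50, True)
        assert object_roll(s, lift) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_rotation_recovered(self):
        n = 200
        angle = np.zeros(n)
        angle[60:] = np.radians(5.0)  # rotate 5 deg after lift at sample 50
        obj1 = np.stack([-5 * np.cos(angle), np.zeros(n), -5 * np.sin(angle)], axis=1)
        obj3 = -obj1
        s = make_series(obj1=obj1, obj3=obj3)
        lift = EventTime(0.5, 50, True)
        assert object_roll(s, lift) == pytest.approx(5.0, abs=1e-9)

    def test_degenerate_edge_geometry_raises(self):
        obj = np.zeros((200, 3))
        s = make_series(obj1=obj, obj3=obj + 0.1)
        with pytest.raises(ValueError, match="degenerate"):
            object_roll(s, EventTime(0.5, 50, True))


class TestInvariances:
    """Detections shift with time shifts; measures ignore rigid translations."""

    def _moving_series(self, n=300, pad=0):
        t = np.arange(n + pad) / FS
        hand = np.zeros((n + pad, 3))
        ramp = np.clip((np.arange(n + pad) - (100 + pad)) / 50, 0, 1)
        hand[:, 2] = 12.0 * ramp  # object rises after sample 100+pad
        obj_off = np.array([5.0, 0, 0])
        pos = {
            "thumb": hand.copy(),
            "index": hand.copy(),
            "obj1": hand - obj_off,
            "obj2": hand.copy(),
            "obj3": hand + obj_off,
        }
        return MarkerTimeSeries(t=t, positions=pos, fs=FS)

    def test_time_shift_equivariance(self):
        base = self._moving_series(pad=0)
        shifted = self._moving_series(pad=17)
        for series, offset in ((base, 0), (shifted, 17)):
            speed = compute_speed(series, ("obj1", "obj2", "obj3"))
            lift = detect_lift_onset(speed, series.t)
            assert lift.valid
            if offset == 0:
                ref = lift.index
            else:
                assert lift.index == ref + 17

    def test_rigid_translation_invariance(self):
        base = self._moving_series()
        translated = MarkerTimeSeries(
            t=base.t,
            positions={k: v + np.array([100.0, -50.0, 30.0]) for k, v in base.positions.items()},
            fs=base.fs,
        )
        for series in (base, translated):
            speed = compute_speed(series, ("obj1", "obj2", "obj3"))
            lift = detect_lift_onset(speed, series.t)
            roll = object_roll(series, lift)
        s0 = compute_speed(base, ("obj1", "obj2", "obj3"))
        s1 = compute_speed(translated, ("obj1", "obj2", "obj3"))
        assert np.allclose(s0, s1)
        assert roll == pytest.approx(object_roll(base, lift))


class TestGapInterpolation:
    def test_short_gap_filled(self):
        pos = np.tile(np.linspace(0, 10, 200)[:, None], (1, 3))
        pos[50:53] = np.nan
        s = make_series(thumb=pos)
        filled = s.interpolate_gaps(max_gap_ms=100)
        assert not np.isnan(filled.positions["thumb"]).any()
        assert filled.positions["thumb"][51, 0] == pytest.approx(pos[49, 0] + 2 * (10 / 199) / 4 * 2, abs=0.2)

    def test_long_gap_rejected(self):
        pos = np.zeros((200, 3))
        pos[50:80] = np.nan
        s = make_series(thumb=pos)
        with pytest.raises(ValueError, match="gap"):
            s.interpolate_gaps(max_gap_ms=100)
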