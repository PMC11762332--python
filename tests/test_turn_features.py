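"""Turn detection, classification, kinematics and the 26-feature vector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drivecog.sensor_io import SyncedTrace
from drivecog.turn_features import (
    FEATURE_NAMES,
    N_FEATURES,
    DetectionParams,
    TurnEvent,
    TurnWindow,
    classify_turn,
    compute_angular_acceleration,
    detect_turn_peaks,
    events_from_session,
    exclude_minor_turns,
    extract_features,
    turn_speed,
)

NO_SMOOTH = DetectionParams(smooth_s=0.0)


def _trace(gz, speed=None, dt=0.1):
    gz = np.asarray(gz, float)
    t = np.arange(len(gz)) * dt
    sp = np.full_like(gz, 10.0) if speed is None else np.asarray(speed, float)
    return SyncedTrace(t=t, gz=gz, speed_interp=sp)


def _window(omega, dt=0.1, peak=None):
    omega = np.asarray(omega, float)
    if peak is None:
        peak = int(np.argmax(np.abs(omega)))
    return TurnWindow(0, peak, len(omega) - 1, omega, dt)


# --- peak detection ---


def test_quiet_trace_yields_no_windows():
    assert detect_turn_peaks(_trace(np.zeros(500)), NO_SMOOTH) == []


def test_single_gaussian_lobe_peak_within_one_sample():
    t = np.arange(0, 30, 0.1)
    gz = 0.6 * np.exp(-((t - 15.0) ** 2) / (2 * 2.0**2))
    params = DetectionParams(threshold=0.2, smooth_s=0.0)
    windows = detect_turn_peaks(_trace(gz), params)
    assert len(windows) == 1
    true_peak = int(np.argmax(np.abs(gz)))  # exhaustive-scan oracle
    assert abs(windows[0].peak_idx - true_peak) <= 1
    assert windows[0].start_idx <= true_peak <= windows[0].end_idx


def test_two_opposite_lobes_detected_separately():
    t = np.arange(0, 30, 0.1)
    gz = 0.6 * np.exp(-((t - 8.0) ** 2) / 2.0) - 0.7 * np.exp(
        -((t - 18.0) ** 2) / 2.0
    )
    windows = detect_turn_peaks(_trace(gz), NO_SMOOTH)
    assert len(windows) == 2
    signs = [np.sign(w.peak_omega) for w in windows]
    assert signs == [1.0, -1.0]
    # windows must not overlap
    assert windows[0].end_idx < windows[1].start_idx


def test_subthreshold_lobe_ignored():
    t = np.arange(0, 20, 0.1)
    gz = 0.1 * np.exp(-((t - 10.0) ** 2) / 2.0)
    assert detect_turn_peaks(_trace(gz), NO_SMOOTH) == []


def test_window_bounds_at_boundary_fraction():
    t = np.arange(0, 40, 0.1)
    gz = 0.8 * np.exp(-((t - 20.0) ** 2) / (2 * 3.0**2))
    params = DetectionParams(threshold=0.2, boundary_frac=0.1, smooth_s=0.0)
    (w,) = detect_turn_peaks(_trace(gz), params)
    inside = np.abs(gz[w.start_idx : w.end_idx + 1])
    assert inside.min() >= 0.1 * 0.8 * 0.95  # at/above the 10% cut
    # one sample beyond each bound is below the cut
    assert abs(gz[w.start_idx - 1]) < 0.1 * 0.8
    assert abs(gz[w.end_idx + 1]) < 0.1 * 0.8


# --- classification ---


@pytest.mark.parametrize(
    "angle,expected",
    [
        (math.pi / 2, "left90"),
        (-math.pi / 2, "right90"),
        (math.pi, "uturn"),
        (-math.pi, "uturn"),
        (0.3, "minor"),
        (-0.3, "minor"),
    ],
)
def test_classification_by_integrated_angle(angle, expected):
    # constant lobe over 2 s: trapezoidal integral is exactly `angle`
    omega = np.full(21, angle / 2.0)
    w = _window(omega)
    assert w.integrated_angle() == pytest.approx(angle, rel=1e-9)
    assert classify_turn(w) == expected


def test_sign_convention_configurable():
    omega = np.full(21, (math.pi / 2) / 2.0)
    w = _window(omega)
    assert classify_turn(w, DetectionParams(left_positive=False)) == "right90"


# --- minor-turn exclusion ---


def _event(turn_type, start, end):
    n = end - start + 1
    return TurnEvent(
        turn_type=turn_type,
        condition="normal",
        peak_omega=0.5,
        alpha_max=0.1,
        alpha_min=-0.1,
        mean_speed=4.0,
        duration=n * 0.1,
        integrated_angle=1.0,
        window=TurnWindow(start, start, end, np.zeros(n), 0.1),
    )


def test_minor_inside_uturn_excluded():
    events = [_event("uturn", 0, 100), _event("minor", 40, 60)]
    assert exclude_minor_turns(events) == [events[0]]


def test_no_minor_events_identity():
    events = [_event("left90", 0, 50), _event("uturn", 100, 200)]
    assert exclude_minor_turns(events) == events


def test_only_minor_events_all_excluded():
    events = [_event("minor", 0, 10), _event("minor", 20, 30)]
    assert exclude_minor_turns(events) == []


def test_nested_quarter_turn_inside_uturn_excluded():
    events = [_event("uturn", 0, 100), _event("left90", 10, 90)]
    assert exclude_minor_turns(events) == [events[0]]


# --- angular acceleration (discrete derivative) ---


def test_alpha_constant_omega_is_zero():
    assert compute_angular_acceleration(_window(np.full(30, 0.5))) == (0.0, 0.0)


def test_alpha_linear_ramp_equals_slope():
    t = np.arange(30) * 0.1
    w = _window(0.5 * t)
    a_max, a_min = compute_angular_acceleration(w)
    assert a_max == pytest.approx(0.5, rel=1e-9)
    assert a_min == pytest.approx(0.5, rel=1e-9)


def test_alpha_triangular_profile():
    up = np.linspace(0.0, 1.0, 11)  # rises 1 rad/s over 1 s
    omega = np.concatenate([up, up[-2::-1]])
    a_max, a_min = compute_angular_acceleration(_window(omega))
    assert a_max == pytest.approx(1.0, rel=1e-9)
    assert a_min == pytest.approx(-1.0, rel=1e-9)


def test_alpha_single_sample_rejected():
    with pytest.raises(ValueError, match="2 samples"):
        compute_angular_acceleration(_window([0.5]))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    omega=st.lists(
        st.floats(min_value=-2, max_value=2, allow_nan=False),
        min_size=2,
        max_size=40,
    )
)
def test_alpha_matches_exhaustive_finite_difference_oracle(omega):
    w = _window(omega)
    a_max, a_min = compute_angular_acceleration(w)
    diffs = [  # brute-force pairwise consecutive differences
        (omega[i + 1] - omega[i]) / 0.1 for i in range(len(omega) - 1)
    ]
    assert a_max == max(diffs)
    assert a_min == min(diffs)


# --- turn speed ---


def test_turn_speed_constant():
    tr = _trace(np.zeros(50), speed=np.full(50, 10.0))
    assert turn_speed(_window(np.zeros(50)), tr) == pytest.approx(10.0)


def test_turn_speed_linear_is_mean():
    sp = np.linspace(0, 10, 51)
    tr = _trace(np.zeros(51), speed=sp)
    w = TurnWindow(0, 25, 50, np.zeros(51), 0.1)
    assert turn_speed(w, tr) == pytest.approx(5.0)


def test_turn_speed_single_sample_window():
    sp = np.linspace(0, 10, 51)
    tr = _trace(np.zeros(51), speed=sp)
    w = TurnWindow(7, 7, 7, np.zeros(1), 0.1)
    assert turn_speed(w, tr) == pytest.approx(sp[7])


# --- end-to-end extraction ---


def test_count_recovery_zero_noise(quiet_session):
    """Every designed turn (6/lap x 10 laps) is recovered, none spurious."""
    events = events_from_session(quiet_session)
    assert len(events) == 60
    kinds = {k: sum(e.turn_type == k for e in events) for k in
             ("left90", "right90", "uturn")}
    assert kinds == {"left90": 20, "right90": 20, "uturn": 20}


def test_parameter_recovery_zero_noise(quiet_session):
    events = events_from_session(quiet_session)
    truth = quiet_session.truth.turns
    ext_w = np.mean([abs(e.peak_omega) for e in events])
    tru_w = np.mean([abs(u.peak_yaw) for u in truth])
    assert ext_w == pytest.approx(tru_w, rel=0.02)
    ext_v = np.mean([e.mean_speed for e in events])
    tru_v = np.mean([u.turn_speed for u in truth])
    assert ext_v == pytest.approx(tru_v, rel=0.02)


def test_parameter_recovery_default_noise(noisy_subject_sessions):
    for sess in noisy_subject_sessions:
        events = events_from_session(sess)
        ext_w = np.mean([abs(e.peak_omega) for e in events])
        tru_w = np.mean([abs(u.peak_yaw) for u in sess.truth.turns])
        assert ext_w == pytest.approx(tru_w, rel=0.10)
        ext_v = np.mean([e.mean_speed for e in events])
        tru_v = np.mean([u.turn_speed for u in sess.truth.turns])
        assert ext_v == pytest.approx(tru_v, rel=0.10)


def test_full_protocol_populates_all_26_features(noisy_subject_sessions):
    fv = extract_features(noisy_subject_sessions)
    assert fv.n_populated == N_FEATURES == 26
    assert len(FEATURE_NAMES) == 26
    # angular-velocity and speed features are unsigned magnitudes
    assert np.all(fv.values[:6] > 0)
    assert np.all(fv.values[18:24] > 0)


def test_missing_condition_flags_13_features(noisy_subject_sessions):
    normal_only = [s for s in noisy_subject_sessions if s.condition == "normal"]
    fv = extract_features(normal_only)
    assert fv.missing.sum() == 13  # the aggressive-condition half
    aggressive_slots = [
        i for i, name in enumerate(FEATURE_NAMES) if "aggressive" in name
    ]
    assert len(aggressive_slots) == 13
    assert all(fv.missing[i] for i in aggressive_slots)


def test_omega_scaling_monotonicity(quiet_session):
    """Scaling gz by c scales angular-velocity features by c; speed fixed.

    c is kept below 1.5 so quarter-turn integrals stay under the 135-degree
    U-turn boundary and the type grouping is unchanged.
    """
    c = 1.2
    scaled = quiet_session.imu.copy()
    scaled["gz"] = scaled["gz"] * c
    from drivecog.synthetic.session import SensorSession

    scaled_sess = SensorSession(
        quiet_session.subject_id, "normal", scaled, quiet_session.gps.copy()
    )
    base = extract_features([quiet_session])
    scal = extract_features([scaled_sess])
    ok = ~base.missing[:6] & ~scal.missing[:6]
    np.testing.assert_allclose(
        scal.values[:6][ok], c * base.values[:6][ok], rtol=1e-6
    )
    ok_sp = ~base.missing[18:21] & ~scal.missing[18:21]
    np.testing.assert_allclose(
        scal.values[18:21][ok_sp], base.values[18:21][ok_sp], rtol=1e-6
    )


def test_extract_rejects_foreign_sessions(noisy_subject_sessions):
    with pytest.raises(ValueError, match="passed to subject"):
        extract_features(noisy_subject_sessions, subject_id="OTHER")
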