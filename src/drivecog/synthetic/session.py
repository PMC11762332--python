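"""Session simulator: multirate IMU/GPS streams for one subject x condition.

The simulated vehicle drives the circuit lap by lap.  Turns are rendered
as trapezoidal yaw-rate lobes (linear ramp in, plateau, linear ramp out)
whose time integral equals the designed heading change exactly; straights
carry zero yaw-rate and a cruise speed adjusted so every lap's path length
equals the circuit's lap length exactly.  Speed is continuous piecewise
linear: it ramps between the cruise speed and each turn's (jittered) turn
speed on the straight before/after the turn, with a short constant-speed
margin around the turn so GPS interpolation inside the turn window is not
contaminated by straight-line speeds.

Channels follow the sensor array being emulated: accelerometer and
gyroscope at 10 Hz, GPS (position + speed) at 1 Hz.  Yaw rate is ``gz``
(Z-axis gyroscope, left turn positive); ``ax`` is longitudinal
acceleration dv/dt, ``ay`` the centripetal term v*omega, ``az`` gravity.
All channels receive additive Gaussian noise per the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .circuit import CircuitError, CircuitSpec, SIGNED_ANGLES, TURN_ANGLES
from .profiles import SubjectProfile

__all__ = ["SensorSession", "SessionTruth", "TurnTruth", "simulate_session"]

IMU_DT = 0.1  # s, 10 Hz
GPS_DT = 1.0  # s, 1 Hz
GRAVITY = 9.80665  # m/s^2

RAMP_S = 1.5  # yaw-rate and speed ramp duration
MARGIN_S = 1.2  # constant turn-speed margin on each side of a turn

#: WGS-84 reference for dead-reckoned GPS coordinates.
ORIGIN_LAT = 33.5
ORIGIN_LON = -112.0
EARTH_RADIUS_M = 6_371_000.0

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
GPS_COLUMNS = ["t", "lat", "lon", "speed"]


@dataclass(frozen=True)
class TurnTruth:
    """Generator ground truth for one executed turn."""

    turn_kind: str  # left90 | right90 | uturn
    lap: int
    t_start: float
    t_end: float
    peak_yaw: float  # signed, rad/s
    turn_speed: float  # m/s
    signed_angle: float  # rad

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SessionTruth:
    """Noise-free internals of a simulated session (not serialized)."""

    turns: list[TurnTruth]
    lap_start_times: list[float]
    path_xy: np.ndarray  # (n, 2) m, at the IMU rate
    heading: np.ndarray  # rad, at the IMU rate
    speed: np.ndarray  # m/s, noise-free, at the IMU rate
    yaw_rate: np.ndarray  # rad/s, noise-free, at the IMU rate

    def path_length(self) -> float:
        """Chord-summed trajectory length over the whole session (m)."""
        return float(
            np.hypot(*np.diff(self.path_xy, axis=0).T).sum()
        )


@dataclass
class SensorSession:
    """One subject x condition recording: IMU at 10 Hz, GPS at 1 Hz."""

    subject_id: str
    condition: str
    imu: pd.DataFrame  # columns t, ax, ay, az, gx, gy, gz
    gps: pd.DataFrame  # columns t, lat, lon, speed
    truth: SessionTruth | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        for name, df, cols in (
            ("imu", self.imu, IMU_COLUMNS),
            ("gps", self.gps, GPS_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} stream missing columns {missing}")
            if len(df) == 0:
                raise ValueError(f"{name} stream is empty")
            t = df["t"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(
                    f"{name} timestamps must be strictly increasing"
                )


def _snap(duration_s: float, minimum: int = 1) -> int:
    """Snap a duration to a whole number of IMU samples."""
    return max(minimum, round(duration_s / IMU_DT))


class _NodeTrack:
    """Piecewise-linear signal described by (sample index, value) nodes."""

    def __init__(self, v0: float):
        self.idx = [0]
        self.val = [v0]

    def hold(self, cur: int, n: int, v: float) -> int:
        self.idx.append(cur + n)
        self.val.append(v)
        return cur + n

    def sample(self, n_samples: int) -> np.ndarray:
        t = np.arange(n_samples, dtype=float)
        return np.interp(t, np.asarray(self.idx, float), np.asarray(self.val))


def simulate_session(
    profile: SubjectProfile,
    circuit: CircuitSpec,
    condition: str,
    seed: int,
) -> SensorSession:
    """Simulate one recording of ``profile`` driving ``circuit``.

    Deterministic given ``(profile, circuit, condition, seed)``.  Raises
    :class:`CircuitError` when the lap length cannot accommodate the
    profile's turn kinematics (turn path distance exceeding the lap).
    """
    if condition not in profile.styles:
        raise ValueError(
            f"unknown condition {condition!r}; profile defines "
            f"{sorted(profile.styles)}"
        )
    rng = np.random.default_rng(seed)
    style = profile.effective_style(condition)

    turn_kinds = [s.kind for s in circuit.turn_segments]
    n_turns = len(turn_kinds)

    # Per-turn jittered kinematics for every lap, in driving order.
    turns_flat: list[tuple[int, str, float, float]] = []
    for lap in range(circuit.laps):
        for kind in turn_kinds:
            jit_v = float(np.clip(rng.normal(1.0, style.jitter_cv), 0.5, 1.5))
            jit_w = float(np.clip(rng.normal(1.0, style.jitter_cv), 0.5, 1.5))
            v_t = style.turn_speed * jit_v
            w_pk = style.peak_yaw(kind) * jit_w
            turns_flat.append((lap, kind, v_t, w_pk))

    ramp_n = _snap(RAMP_S)
    margin_n = _snap(MARGIN_S)

    speed = _NodeTrack(style.straight_speed)
    omega = _NodeTrack(0.0)
    cur = 0
    truths: list[TurnTruth] = []
    lap_starts: list[float] = []

    for lap in range(circuit.laps):
        lap_starts.append(cur * IMU_DT)
        lap_turns = turns_flat[lap * n_turns : (lap + 1) * n_turns]

        # Snap turn phase durations and re-solve the plateau yaw-rate so
        # each turn's integrated heading change is exact on the grid.
        turn_plans = []
        for _, kind, v_t, w_pk in lap_turns:
            theta = TURN_ANGLES[kind]
            hold_n = _snap(theta / w_pk - RAMP_S)
            w_adj = theta / ((hold_n + ramp_n) * IMU_DT)
            sign = 1.0 if SIGNED_ANGLES[kind] > 0 else -1.0
            turn_n = hold_n + 2 * ramp_n
            turn_plans.append((kind, v_t, sign * w_adj, ramp_n, hold_n, turn_n))

        # Fixed (non-cruise) distance this lap, to size straight cruises.
        fixed = 0.0
        for i, (kind, v_t, _, _, _, turn_n) in enumerate(turn_plans):
            fixed += v_t * turn_n * IMU_DT  # the turn itself
            fixed += v_t * margin_n * IMU_DT * 2  # margins both sides
            # speed ramps on the straights bracketing this turn
            fixed += (v_t + style.straight_speed) / 2 * ramp_n * IMU_DT * 2
        first_straight_of_session = lap == 0
        if first_straight_of_session:
            # session starts already at cruise speed: no entry ramp/margin
            v_first = turn_plans[0][1]
            fixed -= v_first * margin_n * IMU_DT
            fixed -= (v_first + style.straight_speed) / 2 * ramp_n * IMU_DT

        cruise_dist = (circuit.lap_length_m - fixed) / n_turns
        if cruise_dist <= 0:
            raise CircuitError(
                "lap length "
                f"{circuit.lap_length_m:.0f} m is too short for the turn "
                f"kinematics (need {fixed:.0f} m of turns/ramps per lap)"
            )
        cruise_n = _snap(cruise_dist / style.straight_speed)

        for i, (kind, v_t, w_signed, r_n, h_n, turn_n) in enumerate(turn_plans):
            v_cruise = cruise_dist / (cruise_n * IMU_DT)
            # --- straight before turn i ---
            if lap == 0 and i == 0:
                cur0 = cur
                cur = speed.hold(cur, cruise_n, v_cruise)
                omega.hold(cur0, cruise_n, 0.0)
            else:
                v_prev = turn_plans[i - 1][1] if i > 0 else prev_lap_last_v
                cur0 = cur
                cur = speed.hold(cur, margin_n, v_prev)  # exit margin
                cur = speed.hold(cur, ramp_n, v_cruise)  # accelerate
                cur = speed.hold(cur, cruise_n, v_cruise)  # cruise
                omega.hold(cur0, cur - cur0, 0.0)  # flat zero across straight
            # decelerate into the turn, then entry margin
            cur0 = cur
            cur = speed.hold(cur, ramp_n, v_t)
            cur = speed.hold(cur, margin_n, v_t)
            omega.hold(cur0, cur - cur0, 0.0)
            # --- the turn ---
            t_start = cur * IMU_DT
            cur = omega.hold(cur, r_n, w_signed)
            cur = omega.hold(cur, h_n, w_signed)
            cur = omega.hold(cur, r_n, 0.0)
            speed.hold(cur - turn_n, turn_n, v_t)
            truths.append(
                TurnTruth(
                    turn_kind=kind,
                    lap=lap,
                    t_start=t_start,
                    t_end=cur * IMU_DT,
                    peak_yaw=w_signed,
                    turn_speed=v_t,
                    signed_angle=SIGNED_ANGLES[kind],
                )
            )
        prev_lap_last_v = turn_plans[-1][1]

    n_samples = cur + 1
    t = np.arange(n_samples) * IMU_DT
    v = speed.sample(n_samples)
    w = omega.sample(n_samples)

    heading = cumulative_trapezoid(w, dx=IMU_DT, initial=0.0)
    vx = v * np.cos(heading)
    vy = v * np.sin(heading)
    x = np.concatenate(
        [[0.0], np.cumsum((vx[:-1] + vx[1:]) / 2 * IMU_DT)]
    )
    y = np.concatenate(
        [[0.0], np.cumsum((vy[:-1] + vy[1:]) / 2 * IMU_DT)]
    )

    noise = profile.noise
    imu = pd.DataFrame(
        {
            "t": t,
            "ax": np.gradient(v, IMU_DT)
            + rng.normal(0, noise.accel_std, n_samples),
            "ay": v * w + rng.normal(0, noise.accel_std, n_samples),
            "az": GRAVITY + rng.normal(0, noise.accel_std, n_samples),
            "gx": rng.normal(0, noise.gyro_std, n_samples),
            "gy": rng.normal(0, noise.gyro_std, n_samples),
            "gz": w + rng.normal(0, noise.gyro_std, n_samples),
        }
    )

    step = round(GPS_DT / IMU_DT)
    gi = np.arange(0, n_samples, step)
    lat = ORIGIN_LAT + np.degrees(y[gi] / EARTH_RADIUS_M)
    lon = ORIGIN_LON + np.degrees(
        x[gi] / (EARTH_RADIUS_M * math.cos(math.radians(ORIGIN_LAT)))
    )
    gps = pd.DataFrame(
        {
            "t": t[gi],
            "lat": lat,
            "lon": lon,
            "speed": v[gi] + rng.normal(0, noise.gps_speed_std, len(gi)),
        }
    )

    truth = SessionTruth(
        turns=truths,
        lap_start_times=lap_starts,
        path_xy=np.column_stack([x, y]),
        heading=heading,
        speed=v,
        yaw_rate=w,
    )
    return SensorSession(
        subject_id=profile.subject_id,
        condition=condition,
        imu=imu,
        gps=gps,
        truth=truth,
    )
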