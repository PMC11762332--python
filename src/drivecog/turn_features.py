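"""Turn detection and the 26-feature kinematic representation.

Turning maneuvers appear as lobes in the Z-axis gyroscope (yaw-rate)
signal.  The pipeline here: detect significant |yaw-rate| peaks, window
each peak out to where the signal decays to a fraction of the peak,
classify the maneuver by its integrated heading change (left/right
quarter turn, U-turn, or a minor adjustment), exclude minor turns and
adjustments nested inside U-turns, compute per-turn kinematics — peak
yaw-rate, angular-acceleration extrema via the discrete derivative
alpha = d(omega)/dt ~ delta(omega)/delta(t), mean GPS speed, duration —
and aggregate per-subject means into a fixed 26-slot feature vector
covering {left, right, U-turn} x {normal, aggressive}, plus U-turn
durations per condition.

Sign convention: left turn = positive yaw (right-handed axes, Z up);
reported angular-velocity features are unsigned magnitudes so left and
right features are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .sensor_io import SyncedTrace, synchronize_gps
from .synthetic.session import SensorSession

__all__ = [
    "DetectionParams",
    "TurnWindow",
    "TurnEvent",
    "FeatureVector",
    "FEATURE_NAMES",
    "N_FEATURES",
    "detect_turn_peaks",
    "classify_turn",
    "exclude_minor_turns",
    "compute_angular_acceleration",
    "turn_speed",
    "events_from_session",
    "extract_features",
    "feature_table",
    "write_feature_table",
    "read_feature_table",
]

TURN_TYPES = ("left90", "right90", "uturn")
CONDITIONS = ("normal", "aggressive")

#: |integrated angle| boundaries (rad): below the first -> minor turn,
#: between -> quarter turn, above the second -> U-turn.  Chosen symmetric
#: around 90 and 180 degrees.
MINOR_ANGLE = np.deg2rad(45.0)
UTURN_ANGLE = np.deg2rad(135.0)


@dataclass(frozen=True)
class DetectionParams:
    """Peak-detection and windowing parameters.

    ``threshold`` is the minimum |yaw-rate| (rad/s) for a peak to count
    as a turn candidate; ``min_separation_s`` suppresses secondary peaks
    closer than this to a larger one; ``boundary_frac`` places window
    bounds where |yaw-rate| first decays below this fraction of the peak;
    ``smooth_s`` is the moving-average width used to stabilize peak
    location and magnitude against sensor noise (0 disables smoothing).
    """

    threshold: float = 0.15
    min_separation_s: float = 2.0
    boundary_frac: float = 0.1
    smooth_s: float = 0.5
    left_positive: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.boundary_frac < 1:
            raise ValueError("boundary_frac must be in (0, 1)")
        if self.min_separation_s < 0 or self.smooth_s < 0:
            raise ValueError("durations must be >= 0")


@dataclass
class TurnWindow:
    """One candidate maneuver on the gyro timeline.

    ``omega`` holds the windowed yaw-rate samples (inclusive of both
    bounds); ``dt`` is the uniform sample spacing.
    """

    start_idx: int
    peak_idx: int
    end_idx: int
    omega: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if not self.start_idx <= self.peak_idx <= self.end_idx:
            raise ValueError("window indices must satisfy start <= peak <= end")
        if len(self.omega) != self.end_idx - self.start_idx + 1:
            raise ValueError("omega length inconsistent with window bounds")

    @property
    def peak_omega(self) -> float:
        """Signed yaw rate at the peak sample."""
        return float(self.omega[self.peak_idx - self.start_idx])

    @property
    def duration(self) -> float:
        return (self.end_idx - self.start_idx) * self.dt

    def integrated_angle(self) -> float:
        """Trapezoidal integral of yaw rate over the window (rad)."""
        return float(np.trapezoid(self.omega, dx=self.dt))


@dataclass(frozen=True)
class TurnEvent:
    """A classified, quantified turning maneuver."""

    turn_type: str  # left90 | right90 | uturn | minor
    condition: str
    peak_omega: float  # signed, rad/s
    alpha_max: float  # rad/s^2
    alpha_min: float  # rad/s^2
    mean_speed: float  # m/s
    duration: float  # s
    integrated_angle: float  # rad
    window: TurnWindow | None = field(compare=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if self.alpha_min > self.alpha_max:
            raise ValueError("alpha_min must be <= alpha_max")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge-shrinking window."""
    if n <= 1:
        return x
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def detect_turn_peaks(
    trace: SyncedTrace, params: DetectionParams | None = None
) -> list[TurnWindow]:
    """Find significant |yaw-rate| peaks and window each maneuver.

    Each returned window contains exactly one dominant peak above
    ``params.threshold``; bounds sit where the (smoothed) |yaw-rate|
    falls below ``boundary_frac`` of the peak, or at the midpoint to an
    adjacent peak, whichever is tighter, so windows never overlap.
    Returns an empty list for quiet traces.
    """
    params = params or DetectionParams()
    if len(trace) == 0:
        raise ValueError("trace is empty")
    gz = np.asarray(trace.gz, float)
    if len(gz) < 2:
        return []
    dt = trace.dt
    n_smooth = int(round(params.smooth_s / dt)) if dt > 0 else 0
    gz_s = _smooth(gz, n_smooth)
    mag = np.abs(gz_s)

    distance = max(1, int(round(params.min_separation_s / dt)))
    peaks, _ = find_peaks(
        mag,
        height=params.threshold,
        distance=distance,
        prominence=params.threshold,
    )
    windows: list[TurnWindow] = []
    for k, p in enumerate(peaks):
        cutoff = params.boundary_frac * mag[p]
        lo_lim = 0 if k == 0 else (peaks[k - 1] + p) // 2 + 1
        hi_lim = len(mag) - 1 if k == len(peaks) - 1 else (p + peaks[k + 1]) // 2
        lo = p
        while lo > lo_lim and mag[lo - 1] >= cutoff:
            lo -= 1
        hi = p
        while hi < hi_lim and mag[hi + 1] >= cutoff:
            hi += 1
        windows.append(
            TurnWindow(
                start_idx=int(lo),
                peak_idx=int(p),
                end_idx=int(hi),
                omega=gz_s[lo : hi + 1].copy(),
                dt=dt,
            )
        )
    return windows


def classify_turn(
    window: TurnWindow, params: DetectionParams | None = None
) -> str:
    """Label a window by its integrated heading change.

    |angle| >= 135 deg -> ``uturn``; 45 deg <= |angle| < 135 deg ->
    ``left90``/``right90`` by sign (left positive by default); otherwise
    ``minor``.
    """
    params = params or DetectionParams()
    angle = window.integrated_angle()
    mag = abs(angle)
    if mag >= UTURN_ANGLE:
        return "uturn"
    if mag >= MINOR_ANGLE:
        leftward = angle > 0 if params.left_positive else angle < 0
        return "left90" if leftward else "right90"
    return "minor"


def exclude_minor_turns(events: list[TurnEvent]) -> list[TurnEvent]:
    """Drop minor turns and any event nested inside a U-turn's window.

    Small steering adjustments within U-turns would otherwise register as
    separate maneuvers and add noise to the per-type means.  Order is
    preserved.
    """
    uturn_spans = [
        (e.window.start_idx, e.window.end_idx)
        for e in events
        if e.turn_type == "uturn" and e.window is not None
    ]

    def nested(e: TurnEvent) -> bool:
        if e.turn_type == "uturn" or e.window is None:
            return False
        return any(
            lo <= e.window.start_idx and e.window.end_idx <= hi
            for lo, hi in uturn_spans
        )

    return [e for e in events if e.turn_type != "minor" and not nested(e)]


def compute_angular_acceleration(window: TurnWindow) -> tuple[float, float]:
    """Angular-acceleration extrema from the discrete derivative.

    alpha between consecutive samples is delta(omega)/delta(t); returns
    ``(alpha_max, alpha_min)`` over the window.  Requires >= 2 samples.
    """
    if len(window.omega) < 2:
        raise ValueError(
            "angular acceleration needs >= 2 samples in the window"
        )
    alpha = np.diff(window.omega) / window.dt
    return float(alpha.max()), float(alpha.min())


def turn_speed(window: TurnWindow, trace: SyncedTrace) -> float:
    """Mean GPS-interpolated speed over the event window (m/s)."""
    return float(
        np.mean(trace.speed_interp[window.start_idx : window.end_idx + 1])
    )


def events_from_session(
    session: SensorSession,
    params: DetectionParams | None = None,
) -> list[TurnEvent]:
    """Full per-session pipeline: detect, classify, quantify, filter."""
    params = params or DetectionParams()
    trace = synchronize_gps(session)
    events: list[TurnEvent] = []
    for w in detect_turn_peaks(trace, params):
        a_max, a_min = compute_angular_acceleration(w)
        events.append(
            TurnEvent(
                turn_type=classify_turn(w, params),
                condition=session.condition,
                peak_omega=w.peak_omega,
                alpha_max=a_max,
                alpha_min=a_min,
                mean_speed=turn_speed(w, trace),
                duration=w.duration,
                integrated_angle=w.integrated_angle(),
                window=w,
            )
        )
    return exclude_minor_turns(events)


def _feature_names() -> list[str]:
    """The 26 feature names, in canonical order."""
    names = []
    words = {
        "left90": "left turns",
        "right90": "right turns",
        "uturn": "U-turns",
    }
    for cond in CONDITIONS:
        for tt in TURN_TYPES:
            names.append(f"avg angular velocity, {cond} {words[tt]}")
    for cond in CONDITIONS:
        for tt in TURN_TYPES:
            names.append(f"max avg angular acceleration, {cond} {words[tt]}")
            names.append(f"min avg angular acceleration, {cond} {words[tt]}")
    for cond in CONDITIONS:
        for tt in TURN_TYPES:
            names.append(f"avg speed, {cond} {words[tt]}")
    for cond in CONDITIONS:
        names.append(f"avg duration, {cond} U-turns")
    return names


FEATURE_NAMES: list[str] = _feature_names()
N_FEATURES = len(FEATURE_NAMES)  # 26
FEATURE_COLUMNS = [f"f{j + 1:02d}" for j in range(N_FEATURES)]


@dataclass
class FeatureVector:
    """The 26-slot per-subject representation.

    ``values[j]`` is NaN where ``missing[j]`` is True (no matching turns
    observed for that slot's condition x turn-type combination).
    Angular-velocity slots are unsigned means of per-turn |peak yaw-rate|;
    acceleration slots are means of per-turn alpha extrema; speed slots
    are means of per-turn mean GPS speed; the last two slots are mean
    U-turn durations per condition.
    """

    subject_id: str
    values: np.ndarray  # shape (26,)
    missing: np.ndarray  # shape (26,), bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.missing = np.asarray(self.missing, bool)
        if self.values.shape != (N_FEATURES,) or self.missing.shape != (
            N_FEATURES,
        ):
            raise ValueError(f"feature vector must have {N_FEATURES} slots")

    @property
    def n_populated(self) -> int:
        return int((~self.missing).sum())


def extract_features(
    sessions: list[SensorSession],
    subject_id: str | None = None,
    params: DetectionParams | None = None,
) -> FeatureVector:
    """Aggregate one subject's sessions into the 26-feature vector.

    ``sessions`` should hold this subject's recordings (typically one
    normal and one aggressive).  Combinations with no observed turns are
    flagged missing rather than zero-filled; imputation is the modeling
    stage's responsibility.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    sid = subject_id or sessions[0].subject_id
    events: list[TurnEvent] = []
    for s in sessions:
        if s.subject_id and sid and s.subject_id != sid:
            raise ValueError(
                f"session for {s.subject_id!r} passed to subject {sid!r}"
            )
        events.extend(events_from_session(s, params))

    by_group: dict[tuple[str, str], list[TurnEvent]] = {}
    for e in events:
        by_group.setdefault((e.condition, e.turn_type), []).append(e)

    def group_mean(cond: str, tt: str, fn) -> float:
        grp = by_group.get((cond, tt))
        return float(np.mean([fn(e) for e in grp])) if grp else np.nan

    values = np.full(N_FEATURES, np.nan)
    j = 0
    for cond in CONDITIONS:
        for tt in TURN_TYPES:
            values[j] = group_mean(cond, tt, lambda e: abs(e.peak_omega))
            j += 1
    for cond in CONDITIONS:
        for tt in TURN_TYPES:
            values[j] = group_mean(cond, tt, lambda e: e.alpha_max)
            values[j + 1] = group_mean(cond, tt, lambda e: e.alpha_min)
            j += 2
    for cond in CONDITIONS:
        for tt in TURN_TYPES:
            values[j] = group_mean(cond, tt, lambda e: e.mean_speed)
            j += 1
    for cond in CONDITIONS:
        values[j] = group_mean(cond, "uturn", lambda e: e.duration)
        j += 1
    return FeatureVector(
        subject_id=sid, values=values, missing=np.isnan(values)
    )


def feature_table(
    vectors: list[FeatureVector], roster: pd.DataFrame
) -> pd.DataFrame:
    """One row per subject: ``subject_id, status, f01..f26, missing_mask``.

    ``missing_mask`` is a 26-character 0/1 string in feature order.
    """
    status = roster.set_index("subject_id")["status"]
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "status": status.get(v.subject_id)}
        for j in range(N_FEATURES):
            row[f"f{j + 1:02d}"] = v.values[j]
        row["missing_mask"] = "".join("1" if m else "0" for m in v.missing)
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"missing_mask": str})
    needed = ["subject_id", "status", *FEATURE_COLUMNS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path}: missing column(s) {missing}")
    return df
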