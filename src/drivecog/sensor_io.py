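"""Sensor-log, roster and manifest I/O plus multirate synchronization.

On-disk formats are plain CSV with mandatory headers:

* IMU log: ``t,ax,ay,az,gx,gy,gz`` (s, m/s^2 x3, rad/s x3) at ~10 Hz;
* GPS log: ``t,lat,lon,speed`` (s, deg, deg, m/s) at ~1 Hz;
* roster: ``subject_id,age,sex,status`` with status Healthy/MCI;
* manifest: ``subject_id,condition,imu_path,gps_path``.

Timestamps are seconds from session start (0-based), not wall clock.
Floats are serialized with 9 significant digits, enough for bit-stable
round-trips at sensor noise scales.

Because GPS runs at 1 Hz against the gyroscope's 10 Hz, downstream turn
analysis needs the two streams on one timeline: :func:`synchronize_gps`
linearly interpolates GPS speed onto the gyro timestamps (clamping to the
nearest edge value outside the GPS span).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic.session import GPS_COLUMNS, IMU_COLUMNS, SensorSession

__all__ = [
    "FormatError",
    "SyncedTrace",
    "read_sensor_log",
    "write_sensor_log",
    "read_roster",
    "write_roster",
    "read_manifest",
    "write_manifest",
    "synchronize_gps",
]

FLOAT_FMT = "%.9g"
ROSTER_COLUMNS = ["subject_id", "age", "sex", "status"]
MANIFEST_COLUMNS = ["subject_id", "condition", "imu_path", "gps_path"]


class FormatError(ValueError):
    """A sensor-log, roster or manifest file violates its schema."""


@dataclass
class SyncedTrace:
    """Gyro-timeline view of one session: yaw rate plus interpolated speed."""

    t: np.ndarray  # s, the gyro (IMU) timeline
    gz: np.ndarray  # rad/s
    speed_interp: np.ndarray  # m/s, GPS speed interpolated onto t

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.gz) == len(self.speed_interp)):
            raise ValueError("t, gz and speed_interp must share one length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Median inter-sample interval (s)."""
        return float(np.median(np.diff(self.t)))


def _validate_stream(
    df: pd.DataFrame, columns: list[str], name: str, path
) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(
            f"{name} log {path}: missing column(s) {', '.join(missing)}"
        )
    if len(df) == 0:
        raise FormatError(f"{name} log {path}: empty channel")
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"{name} log {path}: timestamps not strictly increasing "
            f"at row {int(bad[0]) + 1} (t={t[bad[0]]:g} -> t={t[bad[0] + 1]:g})"
        )
    return df[columns].astype(float)


def session_paths(
    directory: str | Path, subject_id: str, condition: str
) -> tuple[Path, Path]:
    """Conventional (imu_path, gps_path) for one session in a directory."""
    d = Path(directory)
    stem = f"{subject_id}_{condition}"
    return d / f"{stem}_imu.csv", d / f"{stem}_gps.csv"


def write_sensor_log(
    session: SensorSession, imu_path: str | Path, gps_path: str | Path
) -> None:
    """Write one session as an IMU CSV and a GPS CSV."""
    Path(imu_path).parent.mkdir(parents=True, exist_ok=True)
    Path(gps_path).parent.mkdir(parents=True, exist_ok=True)
    session.imu[IMU_COLUMNS].to_csv(
        imu_path, index=False, float_format=FLOAT_FMT
    )
    session.gps[GPS_COLUMNS].to_csv(
        gps_path, index=False, float_format=FLOAT_FMT
    )


def read_sensor_log(
    imu_path: str | Path,
    gps_path: str | Path,
    subject_id: str = "",
    condition: str = "",
) -> SensorSession:
    """Read one session; raises :class:`FormatError` on schema violations."""
    for p in (imu_path, gps_path):
        if not Path(p).exists():
            raise FormatError(f"sensor log not found: {p}")
    imu = _validate_stream(pd.read_csv(imu_path), IMU_COLUMNS, "imu", imu_path)
    gps = _validate_stream(pd.read_csv(gps_path), GPS_COLUMNS, "gps", gps_path)
    return SensorSession(
        subject_id=subject_id, condition=condition, imu=imu, gps=gps
    )


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    roster[ROSTER_COLUMNS].to_csv(path, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"roster {path}: missing column(s) {missing}")
    bad = sorted(set(df["status"]) - {"Healthy", "MCI"})
    if bad:
        raise FormatError(
            f"roster {path}: status must be Healthy or MCI, found {bad}"
        )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"roster {path}: duplicate subject_id(s) {dupes}")
    return df[ROSTER_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path}: missing column(s) {missing}")
    return df[MANIFEST_COLUMNS]


def write_session_dir(
    sessions: list[SensorSession], directory: str | Path
) -> Path:
    """Write all sessions plus a manifest into ``directory``.

    Returns the manifest path.
    """
    directory = Path(directory)
    rows = []
    for s in sessions:
        imu_p, gps_p = session_paths(directory, s.subject_id, s.condition)
        write_sensor_log(s, imu_p, gps_p)
        rows.append(
            {
                "subject_id": s.subject_id,
                "condition": s.condition,
                "imu_path": imu_p.name,
                "gps_path": gps_p.name,
            }
        )
    manifest_path = directory / "manifest.csv"
    write_manifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), manifest_path)
    return manifest_path


def read_session_dir(manifest_path: str | Path) -> list[SensorSession]:
    """Read every session listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    sessions = []
    for row in read_manifest(manifest_path).itertuples(index=False):
        sessions.append(
            read_sensor_log(
                base / row.imu_path,
                base / row.gps_path,
                subject_id=row.subject_id,
                condition=row.condition,
            )
        )
    return sessions


def synchronize_gps(session: SensorSession) -> SyncedTrace:
    """Interpolate 1 Hz GPS speed onto the 10 Hz gyro timeline.

    Piecewise-linear interpolation between GPS samples; gyro timestamps
    outside the GPS span take the nearest edge value.  Requires at least
    two GPS samples.
    """
    gps_t = session.gps["t"].to_numpy(float)
    if len(gps_t) < 2:
        raise ValueError(
            f"GPS stream has {len(gps_t)} sample(s); interpolation "
            "requires at least 2"
        )
    t = session.imu["t"].to_numpy(float)
    speed = np.interp(t, gps_t, session.gps["speed"].to_numpy(float))
    return SyncedTrace(
        t=t, gz=session.imu["gz"].to_numpy(float), speed_interp=speed
    )
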