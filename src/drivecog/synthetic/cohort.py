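"""Cohort generation: a roster plus per-subject, per-condition sessions.

Defaults mirror the pilot study design: 21 subjects (13 healthy, 8 MCI),
each driving the standardized 540 m, 10-lap circuit once per condition
(normal and aggressive).  Every stochastic quantity derives from a single
master seed through stable per-(subject, condition) child seeds, so a
cohort is exactly reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..datasets import pilot_roster
from .circuit import CircuitConfig, build_circuit
from .profiles import (
    CONDITIONS,
    DEFAULT_NOISE,
    NoiseParams,
    StyleParams,
    SubjectProfile,
    default_styles,
)
from .session import SensorSession, simulate_session

__all__ = ["CohortConfig", "generate_cohort", "child_seed", "make_roster"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for a synthetic cohort.

    ``between_subject_cv`` is the coefficient of variation of stable
    per-subject traits (habitual speed and turning sharpness) applied
    multiplicatively to the base style, independent of status — without
    it every subject would share one baseline and the classification
    problem would be degenerate.
    """

    n_healthy: int = 13
    n_mci: int = 8
    conditions: tuple[str, ...] = CONDITIONS
    circuit: CircuitConfig = field(default_factory=CircuitConfig)
    styles: dict[str, StyleParams] = field(default_factory=default_styles)
    noise: NoiseParams = DEFAULT_NOISE
    effect_size: float = 1.0
    between_subject_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_mci < 0:
            raise ValueError("subject counts must be >= 0")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")


def child_seed(master_seed: int, subject_id: str, condition: str) -> int:
    """Stable per-session seed: CRC-32 of ``seed:subject:condition``.

    Deterministic across platforms and Python processes (unlike ``hash``),
    and kept below 2**31.
    """
    key = f"{master_seed}:{subject_id}:{condition}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def make_roster(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Roster for the requested counts.

    The default (13 healthy, 8 MCI) returns the pilot cohort's roster
    verbatim; other counts synthesize demographics (ages uniform on the
    study's 65-85 band, alternating sex) deterministically from ``seed``.
    """
    import numpy as np

    if (config.n_healthy, config.n_mci) == (13, 8):
        return pilot_roster()
    rng = np.random.default_rng(child_seed(seed, "__roster__", "none"))
    statuses = ["Healthy"] * config.n_healthy + ["MCI"] * config.n_mci
    rows = []
    for i, status in enumerate(statuses):
        rows.append(
            {
                "subject_id": f"S{i + 1:02d}",
                "age": int(rng.integers(65, 86)),
                "sex": "Male" if i % 2 == 0 else "Female",
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "age", "sex", "status"])


def _subject_styles(
    base: dict[str, StyleParams],
    cv: float,
    seed: int,
    subject_id: str,
) -> dict[str, StyleParams]:
    """Per-subject trait variation, shared across conditions.

    A stable pace trait scales speed and yaw-rate together — the circuit
    fixes the turning radius, so a driver who takes turns faster must
    also yaw faster — plus a small independent turning-sharpness wiggle
    on yaw-rate only (a quarter of the pace CV).  Factors are clipped to
    +/- 3 CV to keep kinematics physical; status-independent by
    construction.
    """
    if cv == 0:
        return dict(base)
    rng = np.random.default_rng(child_seed(seed, subject_id, "traits"))
    f_pace = float(np.clip(rng.normal(1.0, cv), 1 - 3 * cv, 1 + 3 * cv))
    wiggle_cv = cv / 4
    f_sharp = float(
        np.clip(rng.normal(1.0, wiggle_cv), 1 - 2 * wiggle_cv, 1 + 2 * wiggle_cv)
    )
    f_speed, f_yaw = f_pace, f_pace * f_sharp
    return {
        cond: replace(
            sp,
            turn_speed=sp.turn_speed * f_speed,
            straight_speed=sp.straight_speed * f_speed,
            peak_yaw_90=sp.peak_yaw_90 * f_yaw,
            peak_yaw_uturn=sp.peak_yaw_uturn * f_yaw,
        )
        for cond, sp in base.items()
    }


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SensorSession]]:
    """Generate the roster and all per-subject, per-condition sessions.

    Returns ``(roster, sessions)`` with one session per subject per
    condition, in roster-then-condition order.
    """
    config = config or CohortConfig()
    if config.n_healthy == 0 or config.n_mci == 0:
        warnings.warn(
            "one status group is empty; stratified cross-validation "
            "downstream will not be possible",
            stacklevel=2,
        )
    roster = make_roster(config, seed)
    circuit = build_circuit(config.circuit)
    sessions: list[SensorSession] = []
    for row in roster.itertuples(index=False):
        styles = _subject_styles(
            config.styles, config.between_subject_cv, seed, row.subject_id
        )
        profile = SubjectProfile(
            subject_id=row.subject_id,
            age=int(row.age),
            sex=str(row.sex),
            status=str(row.status),
            styles=styles,
            noise=config.noise,
            effect_size=config.effect_size,
        )
        for condition in config.conditions:
            sessions.append(
                simulate_session(
                    profile,
                    circuit,
                    condition,
                    child_seed(seed, row.subject_id, condition),
                )
            )
    return roster, sessions
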