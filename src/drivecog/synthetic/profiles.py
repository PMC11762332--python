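"""Subject driving-style profiles and the impairment effect model.

Each subject carries one :class:`StyleParams` per driving condition
(normal, aggressive).  Mild cognitive impairment is modeled as a
multiplicative shift on turn speed and peak yaw-rate (slower, more
hesitant turning) plus inflated within-subject variability; both scale
with a dimensionless ``effect_size`` so that ``effect_size = 0`` makes the
two status groups statistically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "StyleParams",
    "NoiseParams",
    "SubjectProfile",
    "default_styles",
    "DEFAULT_NOISE",
    "CONDITIONS",
]

CONDITIONS = ("normal", "aggressive")

#: Fractional reduction of turn speed / peak yaw-rate per unit effect size.
MCI_KINEMATIC_SHIFT = 0.15
#: Fractional inflation of within-subject variability per unit effect size.
MCI_VARIABILITY_INFLATION = 0.30


@dataclass(frozen=True)
class StyleParams:
    """Kinematic style for one driving condition.

    Speeds in m/s, yaw-rates in rad/s.  ``jitter_cv`` is the
    coefficient of variation of lap-to-lap per-turn jitter applied to turn
    speed and peak yaw-rate, so per-subject feature means are estimated
    from genuinely variable maneuvers.
    """

    turn_speed: float
    straight_speed: float
    peak_yaw_90: float
    peak_yaw_uturn: float
    jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("turn_speed", "straight_speed", "peak_yaw_90", "peak_yaw_uturn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")

    def peak_yaw(self, turn_kind: str) -> float:
        return self.peak_yaw_uturn if turn_kind == "uturn" else self.peak_yaw_90


@dataclass(frozen=True)
class NoiseParams:
    """Additive Gaussian sensor noise (per-sample std) per channel group."""

    gyro_std: float = 0.02  # rad/s
    accel_std: float = 0.05  # m/s^2
    gps_speed_std: float = 0.2  # m/s

    def __post_init__(self) -> None:
        for name in ("gyro_std", "accel_std", "gps_speed_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseParams":
        return NoiseParams(
            self.gyro_std * factor,
            self.accel_std * factor,
            self.gps_speed_std * factor,
        )


ZERO_NOISE = NoiseParams(0.0, 0.0, 0.0)
DEFAULT_NOISE = NoiseParams()


def default_styles() -> dict[str, StyleParams]:
    """Default per-condition styles.

    Aggressive driving is sharper and faster: higher turn/straight speeds
    and peak yaw-rates 1.6x the normal condition's.
    """
    normal = StyleParams(
        turn_speed=4.0,
        straight_speed=8.0,
        peak_yaw_90=0.4,
        peak_yaw_uturn=0.6,
    )
    aggressive = StyleParams(
        turn_speed=7.0,
        straight_speed=10.0,
        peak_yaw_90=0.4 * 1.6,
        peak_yaw_uturn=0.6 * 1.6,
    )
    return {"normal": normal, "aggressive": aggressive}


@dataclass(frozen=True)
class SubjectProfile:
    """One subject: identity, demographics, status, and driving style.

    ``effect_size`` scales the impairment model; it only acts when
    ``status == "MCI"``.
    """

    subject_id: str
    age: int
    sex: str
    status: str  # "Healthy" or "MCI"
    styles: dict[str, StyleParams] = field(default_factory=default_styles)
    noise: NoiseParams = DEFAULT_NOISE
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if self.status not in ("Healthy", "MCI"):
            raise ValueError(
                f"status must be 'Healthy' or 'MCI', got {self.status!r}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        shift = MCI_KINEMATIC_SHIFT * self.effect_size
        if self.status == "MCI" and shift >= 1.0:
            raise ValueError(
                f"effect_size {self.effect_size} drives turn kinematics "
                "non-positive"
            )

    def effective_style(self, condition: str) -> StyleParams:
        """Style after applying the status effect for ``condition``.

        Healthy subjects (or ``effect_size = 0``) get the base style
        unchanged; MCI subjects get turn speed and peak yaw-rates scaled by
        ``1 - 0.15 * effect_size`` and jitter CV by
        ``1 + 0.30 * effect_size``.
        """
        base = self.styles[condition]
        if self.status != "MCI" or self.effect_size == 0:
            return base
        kin = 1.0 - MCI_KINEMATIC_SHIFT * self.effect_size
        var = 1.0 + MCI_VARIABILITY_INFLATION * self.effect_size
        return replace(
            base,
            turn_speed=base.turn_speed * kin,
            peak_yaw_90=base.peak_yaw_90 * kin,
            peak_yaw_uturn=base.peak_yaw_uturn * kin,
            jitter_cv=base.jitter_cv * var,
        )
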