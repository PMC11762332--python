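"""Closed test-circuit geometry.

A circuit is an ordered sequence of segments -- straights, quarter turns
(left/right) and 180-degree U-turns -- that closes on itself: the signed
heading changes over one lap sum to +/- 2*pi and the segment arc lengths
sum to the lap length.  The default layout emulates a standardized
assessment loop: a 540 m lap containing two U-turns, two left and two
right quarter turns, with straights padding the remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SegmentKind",
    "Segment",
    "CircuitConfig",
    "CircuitSpec",
    "CircuitError",
    "build_circuit",
    "TURN_ANGLES",
]

#: Unsigned heading change (rad) for each turning segment kind.
TURN_ANGLES = {
    "left90": math.pi / 2,
    "right90": math.pi / 2,
    "uturn": math.pi,
}

#: Signed heading change under the left-positive (right-handed, Z-up)
#: convention.  U-turns default to the left so that one lap closes at +2*pi
#: with the default 2L/2R/2U composition.
SIGNED_ANGLES = {
    "left90": +math.pi / 2,
    "right90": -math.pi / 2,
    "uturn": +math.pi,
}

SegmentKind = str  # one of {"straight", "left90", "right90", "uturn"}


class CircuitError(ValueError):
    """Raised for infeasible or non-closing circuit configurations."""


@dataclass(frozen=True)
class Segment:
    """One circuit element.

    For straights ``length_m`` is the segment length; for turns it is the
    arc length implied by ``turn_radius_m`` and the turn angle.
    """

    kind: SegmentKind
    length_m: float
    turn_radius_m: float | None = None

    @property
    def is_turn(self) -> bool:
        return self.kind in TURN_ANGLES

    @property
    def signed_angle(self) -> float:
        return SIGNED_ANGLES.get(self.kind, 0.0)


@dataclass(frozen=True)
class CircuitConfig:
    """Requested circuit composition.

    ``turn_sequence`` lists turning segments in driving order; straights of
    equal length are inserted between consecutive turns (and wrap around)
    to pad the lap to ``lap_length_m``.
    """

    lap_length_m: float = 540.0
    laps: int = 10
    turn_sequence: tuple[SegmentKind, ...] = (
        "left90",
        "right90",
        "uturn",
        "left90",
        "right90",
        "uturn",
    )
    radius_90_m: float = 10.0
    radius_uturn_m: float = 8.0


@dataclass(frozen=True)
class CircuitSpec:
    """A validated closed circuit: ordered segments, lap length, lap count."""

    segments: tuple[Segment, ...]
    lap_length_m: float
    laps: int

    def __post_init__(self) -> None:
        if self.laps < 1:
            raise CircuitError(f"laps must be >= 1, got {self.laps}")
        total = sum(s.length_m for s in self.segments)
        if not math.isclose(total, self.lap_length_m, rel_tol=1e-6):
            raise CircuitError(
                f"segment arc lengths sum to {total:.6f} m, "
                f"expected lap_length_m = {self.lap_length_m:.6f} m"
            )
        closure = sum(s.signed_angle for s in self.segments)
        if not (
            math.isclose(abs(closure), 2 * math.pi, rel_tol=0, abs_tol=1e-9)
        ):
            raise CircuitError(
                "signed heading changes over one lap sum to "
                f"{closure:.9f} rad; a closed loop requires +/- 2*pi"
            )

    @property
    def turn_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.is_turn)

    @property
    def turns_per_lap(self) -> int:
        return len(self.turn_segments)

    @property
    def heading_closure(self) -> float:
        """Signed heading change over one lap (rad); +/- 2*pi by invariant."""
        return sum(s.signed_angle for s in self.segments)


def build_circuit(config: CircuitConfig | None = None) -> CircuitSpec:
    """Build a closed circuit from a configuration.

    Turning segments take the arc length implied by their radius; equal
    straights are interleaved between turns (one per turn, wrapping) so the
    lap totals ``lap_length_m``.  Raises :class:`CircuitError` when the
    requested turn arcs exceed the lap length or the heading cannot close.
    """
    config = config or CircuitConfig()
    if not config.turn_sequence:
        raise CircuitError(
            "a circuit with zero turns cannot close its heading; "
            "at least one turning segment is required"
        )
    unknown = [k for k in config.turn_sequence if k not in TURN_ANGLES]
    if unknown:
        raise CircuitError(f"unknown turn kinds: {unknown}")

    closure = sum(SIGNED_ANGLES[k] for k in config.turn_sequence)
    if not math.isclose(abs(closure), 2 * math.pi, abs_tol=1e-9):
        raise CircuitError(
            f"turn sequence {config.turn_sequence} yields a lap heading "
            f"change of {closure:.6f} rad; a closed loop requires +/- 2*pi"
        )

    def radius(kind: SegmentKind) -> float:
        return (
            config.radius_uturn_m if kind == "uturn" else config.radius_90_m
        )

    turn_arcs = [TURN_ANGLES[k] * radius(k) for k in config.turn_sequence]
    total_turn = sum(turn_arcs)
    if total_turn > config.lap_length_m:
        raise CircuitError(
            f"turn arcs total {total_turn:.1f} m which exceeds the lap "
            f"length {config.lap_length_m:.1f} m by "
            f"{total_turn - config.lap_length_m:.1f} m"
        )

    n_straights = len(config.turn_sequence)
    straight_len = (config.lap_length_m - total_turn) / n_straights

    segments: list[Segment] = []
    for kind, arc in zip(config.turn_sequence, turn_arcs):
        segments.append(Segment("straight", straight_len))
        segments.append(Segment(kind, arc, turn_radius_m=radius(kind)))
    return CircuitSpec(
        segments=tuple(segments),
        lap_length_m=config.lap_length_m,
        laps=config.laps,
    )
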