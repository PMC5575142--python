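"""Piecewise-constant rate schedules and the rate-interpretation layer.

Laboratory kinetics for sorption, desorption, biodegradation and
volatilization are summarized as staged first-order rates: a per-hour value
that holds on a time segment and switches at breakpoints (e.g. a fast early
desorption stage followed by a slow tail).  A schedule is a step function of
elapsed time covering [0, inf) with no gaps or overlaps.

Two readings of a printed rate are supported:

``probability``
    The value is used directly as a dimensionless per-hour transition
    probability (first-order hourly fraction).  This is the package default
    and the interpretation under which the bundled regimes reproduce the
    modeled elimination outcomes.
``zero_order``
    The value is a constant flux in its printed concentration units,
    convertible between the water and sediment phases via the experimental
    phase sizes (200 mL water per 50 g sediment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ContractError, InvalidRateError, PartitionError

PROBABILITY = "probability"
ZERO_ORDER = "zero_order"


@dataclass(frozen=True)
class Segment:
    """One stage: rate holds on [start, end); end None means unbounded."""

    start: float
    end: float | None
    rate: float

    def __post_init__(self):
        if self.rate < 0:
            raise InvalidRateError(f"negative rate {self.rate} on segment at {self.start} h")
        if self.end is not None and not self.end > self.start:
            raise PartitionError(f"segment [{self.start}, {self.end}) is empty or reversed")

    def contains(self, t: float) -> bool:
        return t >= self.start and (self.end is None or t < self.end)


@dataclass(frozen=True)
class PiecewiseRateSchedule:
    """Per-hour rate of one pathway as a step function of elapsed time.

    Parameters
    ----------
    segments
        Ordered stages partitioning [0, inf).  Left-closed convention: a
        breakpoint at ``b`` belongs to the *later* segment, so a step
        starting at t >= b uses the post-breakpoint rate.
    source, destination
        State labels of the pathway (e.g. water -> sediment for sorption).
    units
        The rate's units as printed in the source experiment
        (informational; interpretation is chosen at matrix build time).
    """

    segments: tuple[Segment, ...]
    source: str
    destination: str
    units: str = "1/h"

    def __post_init__(self):
        if not self.segments:
            raise PartitionError("schedule needs at least one segment")
        if self.segments[0].start != 0:
            raise PartitionError(
                f"first segment starts at {self.segments[0].start} h, must start at 0"
            )
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end is None:
                raise PartitionError(f"unbounded segment at {a.start} h is not last")
            if a.end != b.start:
                kind = "gap" if a.end < b.start else "overlap"
                raise PartitionError(
                    f"{kind} between segments at {a.end} h and {b.start} h"
                )
        if self.segments[-1].end is not None:
            raise PartitionError("last segment must be unbounded (end=None)")

    @classmethod
    def from_breakpoints(
        cls,
        rates: list[float],
        breakpoints: list[float] | None = None,
        *,
        source: str,
        destination: str,
        units: str = "1/h",
    ) -> "PiecewiseRateSchedule":
        """Build from ``n`` rates and ``n-1`` strictly increasing breakpoints."""
        breakpoints = list(breakpoints or [])
        if len(rates) != len(breakpoints) + 1:
            raise ContractError(
                f"{len(rates)} rates need {len(rates) - 1} breakpoints, got {len(breakpoints)}"
            )
        edges = [0.0, *breakpoints, None]
        segments = tuple(
            Segment(start=edges[i], end=edges[i + 1], rate=r) for i, r in enumerate(rates)
        )
        return cls(segments=segments, source=source, destination=destination, units=units)

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(s.start for s in self.segments[1:])

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(s.rate for s in self.segments)

    def rate_at(self, t: float) -> float:
        """Rate governing a step that starts at elapsed time ``t`` (hours)."""
        if t < 0:
            raise ContractError(f"elapsed time must be >= 0, got {t}")
        for seg in self.segments:
            if seg.contains(t):
                return seg.rate
        raise AssertionError("partition invariant violated")  # pragma: no cover

    @property
    def max_rate(self) -> float:
        return max(s.rate for s in self.segments)

    def is_zero(self) -> bool:
        return all(s.rate == 0 for s in self.segments)


@dataclass(frozen=True)
class PhaseContext:
    """Experimental phase sizes used to convert zero-order fluxes between
    the water (ng/mL) and sediment (ng/g) phases."""

    water_volume_mL: float = 200.0
    sediment_mass_g: float = 50.0

    @property
    def sediment_per_water(self) -> float:
        """ng/g gained in sediment per ng/mL removed from water."""
        return self.water_volume_mL / self.sediment_mass_g


def interpret_rate(
    raw_rate: float,
    mode: str = PROBABILITY,
    context: PhaseContext | None = None,
    *,
    from_phase: str = "water",
    to_phase: str = "water",
) -> float:
    """Map a printed rate value onto the model's working scale.

    In ``probability`` mode the value is returned unchanged as a
    dimensionless hourly fraction (it must be < 1).  In ``zero_order`` mode
    the value is a constant flux; if source and destination phases differ it
    is rescaled by the water-to-sediment mass ratio of the experimental
    system (200 mL / 50 g = 4 ng/g per ng/mL).
    """
    if raw_rate < 0:
        raise InvalidRateError(f"rate must be >= 0, got {raw_rate}")
    if mode == PROBABILITY:
        if raw_rate >= 1:
            raise InvalidRateError(
                f"hourly transition probability must be < 1, got {raw_rate}"
            )
        return raw_rate
    if mode == ZERO_ORDER:
        context = context or PhaseContext()
        if from_phase == to_phase:
            return raw_rate
        if (from_phase, to_phase) == ("water", "sediment"):
            return raw_rate * context.sediment_per_water
        if (from_phase, to_phase) == ("sediment", "water"):
            return raw_rate / context.sediment_per_water
        raise ContractError(f"unknown phase pair {from_phase!r} -> {to_phase!r}")
    raise ContractError(f"unknown interpretation mode {mode!r}")
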