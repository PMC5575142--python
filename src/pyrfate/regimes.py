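"""Bundled moisture-regime parameterizations and their validation.

The pyrene system was measured under three seasonal moisture regimes —
normal (average, ~13 °C), wet (~25 °C) and dry (~5 °C) — each with its own
staged rates for the four pathways (sorption water→sediment, desorption
sediment→water, biodegradation in sediment, volatilization from water) and
its own measured initial water concentration.  The parameter sets ship as
human-readable YAML (``pyrfate/data/*.yaml``) in the same schema the
config loader reads, so new pollutants or regimes need no code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigurationError
from .schedule import PiecewiseRateSchedule
from .states import WATER, StateSpace, StateVector

REGIMES = ("normal", "wet", "dry")

#: The four pathways every bundled regime must declare.
PATHWAYS = ("sorption", "desorption", "biodegradation", "volatilization")


@dataclass(frozen=True)
class RegimeParameterSet:
    """One regime's full chain parameterization.

    Attributes
    ----------
    regime
        Label (``normal``/``wet``/``dry`` for the bundled sets; free text
        for user-defined ones).
    space
        The state space the schedules refer to.
    schedules
        Mapping pathway name -> rate schedule.
    u0
        Initial state vector (all mass in the water state for the bundled
        sets: the experiments spike the water phase).
    """

    regime: str
    space: StateSpace
    schedules: dict[str, PiecewiseRateSchedule]
    u0: StateVector

    def __post_init__(self):
        if len(self.u0.values) != self.space.n:
            raise ConfigurationError(
                f"initial vector has {len(self.u0.values)} entries for "
                f"{self.space.n} states"
            )
        for name, sched in self.schedules.items():
            self.space.index(sched.source)
            self.space.index(sched.destination)
            if self.space.is_absorbing(self.space.index(sched.source)):
                raise ConfigurationError(
                    f"pathway {name!r} starts at absorbing state {sched.source!r}"
                )

    def initial_amount(self, label: str) -> float:
        return float(self.u0.values[self.space.index(label)])


def regime_parameters(regime: str) -> RegimeParameterSet:
    """Load one of the three bundled seasonal parameter sets.

    ``normal``: sorption constant 0.0284/h; desorption 0.0538 (<36 h) then
    0.0031; biodegradation 0.0098 (<18 h) then 0.0135; volatilization
    0.0186; initial water 102.05.  ``wet`` and ``dry`` analogously carry
    their measured staged rates and initial concentrations.
    """
    if regime not in REGIMES:
        raise ConfigurationError(
            f"unknown regime {regime!r}; bundled regimes: {REGIMES}"
        )
    from .config import load_config  # local import: config builds on this module

    path = resources.files("pyrfate.data") / f"{regime}.yaml"
    with resources.as_file(path) as p:
        return load_config(p).parameters


@dataclass(frozen=True)
class SegmentReport:
    """Outgoing-probability check for one source state on one time window."""

    source: str
    start: float
    end: float | None
    total_outgoing: float
    valid: bool


@dataclass(frozen=True)
class ValidationReport:
    regime: str
    segments: tuple[SegmentReport, ...]

    @property
    def valid(self) -> bool:
        return all(s.valid for s in self.segments)

    @property
    def max_outgoing(self) -> float:
        return max(s.total_outgoing for s in self.segments)

    def __str__(self) -> str:
        lines = [f"regime {self.regime!r}: {'valid' if self.valid else 'INVALID'}"]
        for s in self.segments:
            end = "inf" if s.end is None else f"{s.end:g}"
            flag = "" if s.valid else "  << outgoing probability >= 1"
            lines.append(
                f"  {s.source:<10} [{s.start:g}, {end}) h: "
                f"total outgoing {s.total_outgoing:.4f}/h{flag}"
            )
        return "\n".join(lines)


def validate_regime(params: RegimeParameterSet) -> ValidationReport:
    """Report the total outgoing hourly probability per source state and
    time window, flagging any window where it reaches 1.

    Schedule partition validity is enforced at construction time, so a
    ``RegimeParameterSet`` that exists already has gap- and overlap-free
    schedules; this report covers the remaining probabilistic constraint.
    """
    by_source: dict[str, list[PiecewiseRateSchedule]] = {}
    for sched in params.schedules.values():
        by_source.setdefault(sched.source, []).append(sched)

    reports: list[SegmentReport] = []
    for source, scheds in by_source.items():
        edges = sorted({0.0} | {b for s in scheds for b in s.breakpoints})
        for i, start in enumerate(edges):
            end = edges[i + 1] if i + 1 < len(edges) else None
            total = sum(s.rate_at(start) for s in scheds)
            reports.append(
                SegmentReport(
                    source=source,
                    start=start,
                    end=end,
                    total_outgoing=total,
                    valid=total < 1.0,
                )
            )
    return ValidationReport(regime=params.regime, segments=tuple(reports))
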