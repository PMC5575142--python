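"""State spaces and state vectors for discrete-time multimedia fate chains.

A chain's state is where a unit of pollutant currently sits: either a
*transient* compartment it can still leave (the water column, the sediment
bed) or an *absorbing* terminal fate it never leaves (volatilized to air,
biodegraded in sediment).  The bundled pyrene system uses four states in a
fixed order: volatilization, biodegradation, water (solvation), sediment
(sorption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ContractError

TRANSIENT = "transient"
ABSORBING = "absorbing"

#: Canonical labels of the pyrene air/water/sediment system, in model order.
VOLATILIZATION = "volatilization"
BIODEGRADATION = "biodegradation"
WATER = "water"
SEDIMENT = "sediment"


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of labelled states, each transient or absorbing.

    Parameters
    ----------
    states
        Sequence of ``(label, kind)`` pairs where kind is ``"transient"``
        or ``"absorbing"``.  Order is the matrix/vector order used
        throughout the package.
    """

    states: tuple[tuple[str, str], ...]

    def __post_init__(self):
        labels = [s[0] for s in self.states]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate state labels in {labels}")
        for label, kind in self.states:
            if kind not in (TRANSIENT, ABSORBING):
                raise ConfigurationError(
                    f"state {label!r}: kind must be transient or absorbing, got {kind!r}"
                )
        if self.k < 1:
            raise ConfigurationError("a chain needs at least one transient state")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.states)

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def k(self) -> int:
        """Number of transient states."""
        return sum(1 for _, kind in self.states if kind == TRANSIENT)

    @property
    def r(self) -> int:
        """Number of absorbing states."""
        return self.n - self.k

    @property
    def transient_indices(self) -> tuple[int, ...]:
        return tuple(i for i, (_, kind) in enumerate(self.states) if kind == TRANSIENT)

    @property
    def absorbing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, (_, kind) in enumerate(self.states) if kind == ABSORBING)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"unknown state label {label!r}; declared states: {self.labels}"
            ) from None

    def is_absorbing(self, i: int) -> bool:
        return self.states[i][1] == ABSORBING


def pyrene_state_space() -> StateSpace:
    """The four-state air/water/sediment system in its canonical order:
    volatilization and biodegradation absorbing, water and sediment transient.
    """
    return StateSpace(
        states=(
            (VOLATILIZATION, ABSORBING),
            (BIODEGRADATION, ABSORBING),
            (WATER, TRANSIENT),
            (SEDIMENT, TRANSIENT),
        )
    )


@dataclass
class StateVector:
    """Pollutant amount per state at elapsed time ``t`` (hours).

    Amounts are in water-phase concentration equivalents (ng/mL of the
    water phase for the bundled pyrene system); the total is conserved
    under propagation by a row-stochastic matrix.
    """

    values: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ContractError("state vector must be one-dimensional")
        if np.any(self.values < 0):
            raise ContractError(f"state vector has negative entries: {self.values}")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "StateVector":
        return StateVector(self.values.copy(), self.t)
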