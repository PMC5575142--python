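"""Absorbing Markov-chain core: transition matrices, propagation, and
closed-form absorption analytics.

The fate of a pollutant in a multimedia system is modeled as a discrete-time
Markov chain over labelled states.  Each hour, mass in a transient
compartment either stays put or moves along a pathway with a fixed
probability; absorbing states (volatilized, biodegraded) keep everything
they receive.  With the states ordered so that absorbing states come first,
the transition matrix has the canonical block form::

        P = [ I  O ]      I: r x r identity        O: r x k zeros
            [ R  Q ]      R: k x r  transient -> absorbing
                          Q: k x k  transient -> transient

Standard absorbing-chain theory then gives the fundamental matrix
N = (I - Q)^-1 (expected visits to each transient state) and the absorption
probability matrix B = N R (probability of ultimately ending in each
absorbing state, per starting transient state).  For time-homogeneous
rates, B is the closed-form counterpart of iterating U(t + t0) = U(t) P,
and the two are used as mutual cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import (
    ContractError,
    DecompositionError,
    InvalidRateError,
    NoAbsorptionError,
)
from .schedule import PiecewiseRateSchedule
from .states import StateSpace, StateVector

#: Row sums must match 1 to this absolute tolerance; a row further off is an
#: error at construction time, never silently renormalized.
ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-step transition matrix over a state space.

    Attributes
    ----------
    P
        n x n array, ``P[i, j]`` = probability that mass in state i is in
        state j one step later.
    space
        State ordering and transient/absorbing tags.
    t0
        Step length in hours.
    """

    P: np.ndarray
    space: StateSpace
    t0: float = 1.0

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        n = self.space.n
        if P.shape != (n, n):
            raise ContractError(f"matrix shape {P.shape} != ({n}, {n})")
        if self.t0 <= 0:
            raise ContractError(f"step length t0 must be > 0, got {self.t0}")
        if np.any(P < 0) or np.any(P > 1):
            raise InvalidRateError("transition probabilities must lie in [0, 1]")
        rows = P.sum(axis=1)
        bad = np.where(np.abs(rows - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            i = int(bad[0])
            raise InvalidRateError(
                f"row {i} ({self.space.labels[i]!r}) sums to {rows[i]!r}, not 1"
            )
        for i in self.space.absorbing_indices:
            row = np.zeros(n)
            row[i] = 1.0
            if not np.array_equal(P[i], row):
                raise InvalidRateError(
                    f"absorbing state {self.space.labels[i]!r} must have an "
                    f"identity row, got {P[i]}"
                )

    @property
    def n(self) -> int:
        return self.space.n


def build_transition_matrix(
    schedules: Mapping[str, PiecewiseRateSchedule],
    space: StateSpace,
    t: float = 0.0,
    t0: float = 1.0,
) -> TransitionMatrix:
    """Assemble the one-step matrix in force for a step starting at time ``t``.

    Each pathway contributes its scheduled rate at ``t`` (times ``t0``) as
    the off-diagonal entry source -> destination; the diagonal of each
    transient row is the complement so the row sums to one, and absorbing
    rows are identity.  Rates are read as dimensionless per-hour transition
    probabilities (the package's default interpretation of staged
    first-order rates).

    Raises
    ------
    InvalidRateError
        If a source state's total outgoing probability over the step
        reaches 1.
    ConfigurationError
        If a schedule references an undeclared state.
    """
    if t < 0:
        raise ContractError(f"time must be >= 0, got {t}")
    n = space.n
    P = np.zeros((n, n))
    for i in space.absorbing_indices:
        P[i, i] = 1.0
    outgoing = np.zeros(n)
    for name, sched in schedules.items():
        i = space.index(sched.source)
        j = space.index(sched.destination)
        if space.is_absorbing(i):
            raise ContractError(
                f"pathway {name!r} leaves absorbing state {sched.source!r}"
            )
        if i == j:
            raise ContractError(f"pathway {name!r} maps {sched.source!r} onto itself")
        p = sched.rate_at(t) * t0
        P[i, j] += p
        outgoing[i] += p
    for i in space.transient_indices:
        if outgoing[i] >= 1.0:
            raise InvalidRateError(
                f"total outgoing probability from {space.labels[i]!r} at "
                f"t={t} h is {outgoing[i]:.4f} >= 1"
            )
        P[i, i] = 1.0 - outgoing[i]
    return TransitionMatrix(P=P, space=space, t0=t0)


def step(u: StateVector, P: TransitionMatrix) -> StateVector:
    """One propagation step: ``U(t + t0) = U(t) P``, time advanced by t0.

    Total mass is conserved exactly up to floating point because P is
    row-stochastic.
    """
    if len(u.values) != P.n:
        raise ContractError(
            f"state vector length {len(u.values)} != matrix size {P.n}"
        )
    return StateVector(values=u.values @ P.P, t=u.t + P.t0)


def canonical_decomposition(
    P: TransitionMatrix, space: StateSpace | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (Q, R) blocks of the canonical form.

    Returns
    -------
    Q : (k, k) ndarray
        Transient -> transient probabilities, in transient order.
    R : (k, r) ndarray
        Transient -> absorbing probabilities, in absorbing order.
    """
    space = space or P.space
    if space.labels != P.space.labels:
        raise ContractError("state space does not match the matrix's")
    if space.r == 0:
        raise DecompositionError("no absorbing state: canonical form undefined")
    ti = np.asarray(space.transient_indices)
    ai = np.asarray(space.absorbing_indices)
    Q = P.P[np.ix_(ti, ti)].copy()
    R = P.P[np.ix_(ti, ai)].copy()
    return Q, R


def reassemble(Q: np.ndarray, R: np.ndarray, space: StateSpace, t0: float = 1.0) -> TransitionMatrix:
    """Inverse of :func:`canonical_decomposition`: rebuild the full matrix
    from its blocks (identity rows for absorbing states, zero O block)."""
    n = space.n
    P = np.zeros((n, n))
    ti = np.asarray(space.transient_indices)
    ai = np.asarray(space.absorbing_indices)
    for i in ai:
        P[i, i] = 1.0
    P[np.ix_(ti, ti)] = Q
    P[np.ix_(ti, ai)] = R
    return TransitionMatrix(P=P, space=space, t0=t0)


def fundamental_matrix(Q: np.ndarray) -> np.ndarray:
    """Fundamental matrix ``N = (I - Q)^-1`` of an absorbing chain.

    ``N[i, j]`` is the expected number of visits to transient state j
    starting from transient state i before absorption.  Requires the
    spectral radius of Q to be < 1, i.e. every transient state must have
    some escape route to absorption.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ContractError(f"Q must be square, got shape {Q.shape}")
    rho = np.max(np.abs(np.linalg.eigvals(Q))) if Q.size else 0.0
    if rho >= 1.0 - 1e-12:
        raise NoAbsorptionError(
            f"spectral radius of Q is {rho:.6f} >= 1: some transient state "
            "cannot reach absorption"
        )
    N = np.linalg.inv(np.eye(Q.shape[0]) - Q)
    return N


def absorption_probabilities(N: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Ultimate absorption probabilities ``B = N R``.

    ``B[i, j]`` is the probability that mass starting in transient state i
    is eventually captured by absorbing state j; rows sum to one because
    absorption is certain when the fundamental matrix exists.
    """
    N = np.asarray(N, dtype=float)
    R = np.asarray(R, dtype=float)
    if N.shape[0] != N.shape[1] or R.shape[0] != N.shape[0]:
        raise ContractError(f"incompatible shapes N {N.shape}, R {R.shape}")
    return N @ R
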