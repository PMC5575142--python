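"""Synthetic laboratory kinetics and staged-rate recovery.

The staged rates driving the chain are, in the source experiments, derived
from concentration-vs-time curves of four bench kinetics experiments
(sorption, desorption, in-sediment biodegradation, volatilization).  This
module emulates those curves — piecewise first-order decay with
multiplicative lognormal measurement noise — and recovers staged per-hour
rates from them by segmented log-linear regression with exhaustive
breakpoint search.  It both documents the assumed statistical structure of
the inputs and provides the parameter-recovery test bed for the pipeline.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, FitDomainError
from .regimes import PATHWAYS, RegimeParameterSet
from .schedule import PiecewiseRateSchedule, Segment
from .states import StateVector, pyrene_state_space

#: Concentrations below this are censored at the floor before the log
#: transform, mimicking a quantification detection limit (ng/mL).
DETECTION_FLOOR = 0.1

#: Default measurement noise, as a coefficient of variation.  Matches the
#: duplicate-experiment quality-control bound (relative SD < 15%).
DEFAULT_NOISE_CV = 0.15

EXPERIMENTS = ("sorption", "desorption", "biodegradation", "volatility")


@dataclass(frozen=True)
class ConcentrationSeries:
    """One synthetic experiment: concentration sampled over time.

    ``concentrations`` are ng/mL for water-phase experiments (sorption,
    volatility) and ng/g for sediment-phase ones (desorption,
    biodegradation).
    """

    times: np.ndarray
    concentrations: np.ndarray
    experiment: str
    noise_cv: float
    seed: int

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ContractError("times and concentrations must be equal-length 1-D")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ContractError("times must start at 0 and be strictly increasing")
        if np.any(c < 0):
            raise ContractError("concentrations must be >= 0")

    def to_frame(self, unit: str = "ng/mL", replicate: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "concentration": self.concentrations,
                "unit": unit,
                "experiment": self.experiment,
                "replicate": replicate,
            }
        )

    def to_csv(self, path, unit: str = "ng/mL", replicate: int = 0) -> None:
        self.to_frame(unit=unit, replicate=replicate).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_h"].to_numpy(dtype=float),
            concentrations=df["concentration"].to_numpy(dtype=float),
            experiment=str(df["experiment"].iloc[0]) if "experiment" in df else "unknown",
            noise_cv=float("nan"),
            seed=-1,
        )


def _noiseless_decay(schedule: PiecewiseRateSchedule, c0: float, times: np.ndarray) -> np.ndarray:
    """Continuous piecewise-exponential decay: within each stage starting at
    breakpoint b, c(t) = c(b) exp(-rate (t - b))."""
    edges = [0.0, *schedule.breakpoints]
    c_at_edge = [c0]
    for i in range(1, len(edges)):
        dt = edges[i] - edges[i - 1]
        c_at_edge.append(c_at_edge[-1] * math.exp(-schedule.rates[i - 1] * dt))
    out = np.empty_like(times, dtype=float)
    for i, t in enumerate(times):
        j = int(np.searchsorted(edges, t, side="right")) - 1
        out[i] = c_at_edge[j] * math.exp(-schedule.rates[j] * (t - edges[j]))
    return out


def _noiseless_linear(schedule: PiecewiseRateSchedule, c0: float, times: np.ndarray) -> np.ndarray:
    """Zero-order alternative: straight-line decline at the staged rate,
    clipped at zero."""
    edges = [0.0, *schedule.breakpoints]
    c_at_edge = [c0]
    for i in range(1, len(edges)):
        dt = edges[i] - edges[i - 1]
        c_at_edge.append(max(0.0, c_at_edge[-1] - schedule.rates[i - 1] * dt))
    out = np.empty_like(times, dtype=float)
    for i, t in enumerate(times):
        j = int(np.searchsorted(edges, t, side="right")) - 1
        out[i] = max(0.0, c_at_edge[j] - schedule.rates[j] * (t - edges[j]))
    return out


def generate_decay_series(
    schedule: PiecewiseRateSchedule,
    c0: float,
    times: np.ndarray,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
    experiment: str = "volatility",
    kinetics: str = "first_order",
) -> ConcentrationSeries:
    """Sample a synthetic concentration series from a staged-rate schedule.

    The noiseless signal follows piecewise first-order decay (or piecewise
    linear decline with ``kinetics="zero_order"``); each observation is
    multiplied by unit-mean lognormal noise with coefficient of variation
    ``noise_cv``.  The same seed always yields the identical series.
    """
    if c0 <= 0:
        raise ContractError(f"c0 must be > 0, got {c0}")
    if noise_cv < 0:
        raise ContractError(f"noise_cv must be >= 0, got {noise_cv}")
    times = np.asarray(times, dtype=float)
    if kinetics == "first_order":
        clean = _noiseless_decay(schedule, c0, times)
    elif kinetics == "zero_order":
        clean = _noiseless_linear(schedule, c0, times)
    else:
        raise ContractError(f"unknown kinetics {kinetics!r}")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=times.size)
        obs = clean * noise
    else:
        obs = clean
    return ConcentrationSeries(
        times=times,
        concentrations=obs,
        experiment=experiment,
        noise_cv=noise_cv,
        seed=seed,
    )


@dataclass(frozen=True)
class SegmentedRateFit:
    """Result of a segmented log-linear rate fit."""

    breakpoints: tuple[float, ...]
    segment_rates: tuple[float, ...]
    c0: float
    residual: float  # residual sum of squares on the log scale
    n_segments: int

    def __post_init__(self):
        if len(self.segment_rates) != len(self.breakpoints) + 1:
            raise ContractError("n rates must be n breakpoints + 1")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ContractError("breakpoints must be strictly increasing")
        if any(r < 0 for r in self.segment_rates):
            raise ContractError("fitted rates must be >= 0")

    def to_schedule(self, source: str, destination: str, units: str = "1/h") -> PiecewiseRateSchedule:
        return PiecewiseRateSchedule.from_breakpoints(
            list(self.segment_rates),
            list(self.breakpoints),
            source=source,
            destination=destination,
            units=units,
        )

    def to_dict(self) -> dict:
        return {
            "breakpoints_h": list(self.breakpoints),
            "segment_rates_per_h": list(self.segment_rates),
            "c0": self.c0,
            "log_rss": self.residual,
            "n_segments": self.n_segments,
        }


def _fit_fixed_breakpoints(
    t: np.ndarray, logc: np.ndarray, breaks: tuple[float, ...]
) -> tuple[np.ndarray, float, float]:
    """Least-squares fit of a continuous piecewise-linear model on the log
    scale with given breakpoints: logc ~ log c0 - sum_j r_j * overlap_j(t).
    Returns (rates, log_c0, rss).  Rates are clamped at zero (a negative
    decay constant is outside the model family)."""
    edges = [0.0, *breaks, math.inf]
    cols = []
    for j in range(len(breaks) + 1):
        lo, hi = edges[j], edges[j + 1]
        cols.append(np.clip(t, lo, hi) - lo)  # time spent inside segment j
    X = np.column_stack([np.ones_like(t), *[-c for c in cols]])
    beta, *_ = np.linalg.lstsq(X, logc, rcond=None)
    rates = np.maximum(beta[1:], 0.0)
    pred = X @ np.concatenate([[beta[0]], rates])
    rss = float(np.sum((logc - pred) ** 2))
    return rates, float(beta[0]), rss


def fit_segmented_rates(
    series: ConcentrationSeries,
    max_segments: int = 3,
    floor: float = DETECTION_FLOOR,
    min_points: int = 3,
    parsimony: float = 0.05,
) -> SegmentedRateFit:
    """Recover staged per-hour decay rates from a concentration series.

    Fits continuous piecewise log-linear models for 1..``max_segments``
    segments, choosing breakpoints by exhaustive search over interior
    observation times (each candidate segment must contain at least
    ``min_points`` observations).  The reported model is the smallest
    number of segments whose residual sum of squares is within
    ``parsimony`` (relative) of the best achieved at ``max_segments`` — a
    stated, deterministic parsimony rule.

    Concentrations are censored at ``floor`` before the log transform,
    mimicking a detection limit.
    """
    if max_segments < 1:
        raise ContractError("max_segments must be >= 1")
    t = series.times
    c = np.maximum(series.concentrations, floor)
    if np.any(c <= 0):
        raise FitDomainError("non-positive concentrations survive the floor")
    logc = np.log(c)

    best_by_k: dict[int, tuple[float, tuple[float, ...], np.ndarray, float]] = {}
    interior = t[1:-1]
    for k in range(1, max_segments + 1):
        best: tuple | None = None
        for breaks in itertools.combinations(interior, k - 1):
            edges = [t[0], *breaks, t[-1]]
            counts = [
                int(np.sum((t >= lo) & (t < hi))) for lo, hi in zip(edges, edges[1:])
            ]
            counts[-1] += 1  # last segment includes the final observation
            if min(counts) < min_points:
                continue
            rates, logc0, rss = _fit_fixed_breakpoints(t, logc, breaks)
            if best is None or rss < best[0]:
                best = (rss, breaks, rates, logc0)
        if best is not None:
            best_by_k[k] = best
    if not best_by_k:
        raise ContractError(
            f"no candidate segmentation leaves {min_points} observations per segment"
        )

    k_max = max(best_by_k)
    rss_floor = best_by_k[k_max][0]
    chosen_k = k_max
    for k in sorted(best_by_k):
        rss_k = best_by_k[k][0]
        if rss_k <= rss_floor * (1 + parsimony) or rss_k <= rss_floor + 1e-12:
            chosen_k = k
            break
    rss, breaks, rates, logc0 = best_by_k[chosen_k]
    return SegmentedRateFit(
        breakpoints=tuple(float(b) for b in breaks),
        segment_rates=tuple(float(r) for r in rates),
        c0=float(math.exp(logc0)),
        residual=rss,
        n_segments=chosen_k,
    )


def random_regime(
    seed: int,
    rate_bounds: tuple[float, float] = (0.001, 0.2),
    max_segments: int = 3,
    horizon_for_breaks: float = 96.0,
) -> RegimeParameterSet:
    """Seed-deterministic random parameter set for property tests.

    Draws 1-3 stages per pathway with rates in ``rate_bounds`` and integer
    breakpoints, then rescales any source state whose total outgoing hourly
    probability would reach 1.  Always passes :func:`~pyrfate.regimes.validate_regime`.
    """
    lo, hi = rate_bounds
    if not (0 <= lo <= hi):
        raise ContractError(f"infeasible rate bounds ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    space = pyrene_state_space()
    topology = {
        "sorption": ("water", "sediment"),
        "desorption": ("sediment", "water"),
        "biodegradation": ("sediment", "biodegradation"),
        "volatilization": ("water", "volatilization"),
    }
    schedules: dict[str, PiecewiseRateSchedule] = {}
    for name in PATHWAYS:
        src, dst = topology[name]
        n_seg = int(rng.integers(1, max_segments + 1))
        rates = rng.uniform(lo, hi, size=n_seg)
        breaks = np.sort(
            rng.choice(np.arange(1, int(horizon_for_breaks)), size=n_seg - 1, replace=False)
        ).astype(float)
        schedules[name] = PiecewiseRateSchedule.from_breakpoints(
            list(rates), list(breaks), source=src, destination=dst
        )
    # rescale so every source's worst-case outgoing probability stays < 1
    for src in ("water", "sediment"):
        worst = sum(s.max_rate for s in schedules.values() if s.source == src)
        if worst >= 0.999:
            factor = 0.999 / worst
            for name, s in list(schedules.items()):
                if s.source == src:
                    schedules[name] = PiecewiseRateSchedule(
                        segments=tuple(
                            Segment(seg.start, seg.end, seg.rate * factor)
                            for seg in s.segments
                        ),
                        source=s.source,
                        destination=s.destination,
                        units=s.units,
                    )
    u0 = np.zeros(space.n)
    u0[space.index("water")] = rng.uniform(50.0, 150.0)
    return RegimeParameterSet(
        regime=f"random-{seed}",
        space=space,
        schedules=schedules,
        u0=StateVector(u0),
    )
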