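"""Hazard-scale conversions between published risk formats and per-step probabilities.

Published evidence arrives in heterogeneous metrics: cumulative risks over some
horizon ("27% within 10 years"), lifetime risks, hazard ratios, and relative
risk reductions.  The simulation engine works on a discrete time grid, so every
input has to be converted into a per-step event probability.  The conversions
here assume a piecewise-constant hazard within each published segment:

    rate(p, o) = -ln(1 - p) / o            cumulative risk -> constant rate
    q(rate, c) = 1 - exp(-rate * c)        rate -> probability over c years
    S_adj      = S_ref ** hr               hazard-ratio survival adjustment

Composing the per-step probabilities produced by :func:`stepwise_probabilities`
reproduces the published cumulative risks exactly at every segment boundary,
and is invariant to the choice of step length (a 1-year grid and a 2.5-year
grid agree at common time points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "annual_rate",
    "interval_probability",
    "apply_hazard_ratio",
    "stepwise_probabilities",
    "RiskEstimate",
    "RiskSchedule",
]


def annual_rate(p: float, o: float) -> float:
    """Constant annual event rate implied by cumulative probability *p* over *o* years.

    Parameters
    ----------
    p : float
        Cumulative event probability, ``0 <= p < 1``.  A probability of 1 has
        no finite rate and is rejected.
    o : float
        Horizon in years over which *p* accrues; must be positive.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {p}")
    if o <= 0:
        raise ValueError(f"horizon must be positive, got {o}")
    return -math.log1p(-p) / o


def interval_probability(rate: float, c: float) -> float:
    """Event probability over an interval of *c* years under a constant *rate*."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if c <= 0:
        raise ValueError(f"interval length must be positive, got {c}")
    return -math.expm1(-rate * c)


def apply_hazard_ratio(ref_survival: float, hr: float) -> float:
    """Survival of a group with hazard ratio *hr* relative to reference survival.

    ``S = ref ** hr``: under proportional hazards the adjusted survival is the
    reference survival raised to the hazard ratio.
    """
    if not 0.0 < ref_survival <= 1.0:
        raise ValueError(f"reference survival must be in (0, 1], got {ref_survival}")
    if hr < 0:
        raise ValueError(f"hazard ratio must be non-negative, got {hr}")
    return ref_survival**hr


@dataclass(frozen=True)
class RiskEstimate:
    """A published cumulative risk: probability *p* of the event within *o* years."""

    p: float
    o: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"cumulative probability must be in [0, 1), got {self.p}")
        if self.o <= 0:
            raise ValueError(f"horizon must be positive, got {self.o}")

    @property
    def rate(self) -> float:
        return annual_rate(self.p, self.o)


@dataclass(frozen=True)
class RiskSchedule:
    """Piecewise cumulative risk: ordered ``(horizon_end_year, cumulative_p)`` segments.

    The hazard is constant within each segment; beyond the last published
    horizon the final segment's hazard is extended indefinitely.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a risk schedule needs at least one segment")
        object.__setattr__(
            self, "segments", tuple((float(h), float(p)) for h, p in self.segments)
        )
        prev_h, prev_p = 0.0, 0.0
        for h, p in self.segments:
            if h <= prev_h:
                raise ValueError(f"segment horizons must be strictly increasing: {h}")
            if not 0.0 <= p < 1.0:
                raise ValueError(f"cumulative probability must be in [0, 1), got {p}")
            if p < prev_p:
                raise ValueError("cumulative probabilities must be non-decreasing")
            prev_h, prev_p = h, p

    @classmethod
    def from_pairs(cls, pairs) -> "RiskSchedule":
        return cls(tuple((float(h), float(p)) for h, p in pairs))

    def to_pairs(self) -> list[list[float]]:
        return [[h, p] for h, p in self.segments]

    @property
    def segment_rates(self) -> tuple[float, ...]:
        """Constant hazard within each segment."""
        rates = []
        prev_h, prev_lam = 0.0, 0.0
        for h, p in self.segments:
            lam = -math.log1p(-p)
            rates.append((lam - prev_lam) / (h - prev_h))
            prev_h, prev_lam = h, lam
        return tuple(rates)

    def cumulative_hazard(self, t: float) -> float:
        """Integrated hazard up to time *t* (last segment extended beyond schedule)."""
        if t < 0:
            raise ValueError("time must be non-negative")
        lam = 0.0
        prev_h = 0.0
        rates = self.segment_rates
        for (h, _p), r in zip(self.segments, rates):
            if t <= h:
                return lam + r * (t - prev_h)
            lam += r * (h - prev_h)
            prev_h = h
        return lam + rates[-1] * (t - prev_h)

    def cumulative_probability(self, t: float) -> float:
        return -math.expm1(-self.cumulative_hazard(t))

    def step_hazards(self, step: float, horizon: float) -> np.ndarray:
        """Integrated hazard of each step interval on the grid ``step, 2*step, ...``."""
        n = _n_steps(step, horizon)
        bounds = np.array([self.cumulative_hazard(k * step) for k in range(n + 1)])
        return np.diff(bounds)

    def step_rates(self, step: float, horizon: float) -> np.ndarray:
        """Average hazard rate per year within each step interval."""
        return self.step_hazards(step, horizon) / step


def _n_steps(step: float, horizon: float) -> int:
    if step <= 0 or horizon <= 0:
        raise ValueError("step and horizon must be positive")
    n = round(horizon / step)
    if abs(n * step - horizon) > 1e-9 or n < 1:
        raise ValueError(f"step {step} does not divide horizon {horizon}")
    return n


def stepwise_probabilities(
    schedule: RiskSchedule, step: float, horizon: float
) -> np.ndarray:
    """Per-step conditional event probabilities reproducing *schedule* cumulatively.

    Returns an array ``q`` of length ``horizon/step`` such that
    ``1 - prod(1 - q[:k])`` equals the schedule's cumulative probability at
    ``k * step`` for every k (to floating-point accuracy).
    """
    return -np.expm1(-schedule.step_hazards(step, horizon))
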