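"""Mammographic screening sensitivity and negative-screen histories.

Sensitivity at a screen is a logistic function of the tumour's diameter at
that screen, zero below the minimal detectable diameter (0.5 mm).  A history
of negative screens before diagnosis enters the likelihood by *backward
projection*: the deterministic exponential growth law gives the tumour's
size at each past screen from its size at detection and its inverse growth
rate, and each negative screen contributes one minus the sensitivity at that
back-projected size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .geometry import D0, V0

__all__ = ["ScreeningParams", "ScreeningHistory", "sensitivity", "negative_screens_likelihood"]


@dataclass(frozen=True)
class ScreeningParams:
    """Logistic sensitivity: expit(beta1 + beta2 * diameter_mm) above D0."""

    beta1: float
    beta2: float

    def __post_init__(self):
        if not (np.isfinite(self.beta1) and np.isfinite(self.beta2)):
            raise ValueError("screening coefficients must be finite")


@dataclass(frozen=True)
class ScreeningHistory:
    """Offsets (years before diagnosis, positive, increasing) of negative screens."""

    times_before_dx: tuple = field(default_factory=tuple)

    def __post_init__(self):
        t = tuple(float(x) for x in self.times_before_dx)
        if any(x <= 0 for x in t):
            raise ValueError("screen offsets must be positive years before diagnosis")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("screen offsets must be strictly increasing into the past")
        object.__setattr__(self, "times_before_dx", t)

    def __len__(self):
        return len(self.times_before_dx)


def sensitivity(d, params: ScreeningParams):
    """Probability that a screen detects a tumour of diameter ``d`` mm."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    return np.where(d <= D0, 0.0, expit(params.beta1 + params.beta2 * d))


def negative_screens_likelihood(history: ScreeningHistory, v, r, params: ScreeningParams):
    """P(all listed screens negative | volume v at diagnosis, inverse rate r).

    Each screen at offset ``delta`` saw the tumour at volume ``v * exp(-delta/r)``;
    screens that pre-date detectability (or tumour onset) contribute a factor 1.
    Empty history returns exactly 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    if float(np.min(np.asarray(v))) < V0 * (1 - 1e-12):
        raise ValueError("volume at diagnosis must be at least V0")
    out = np.ones(np.broadcast_shapes(np.shape(r), np.shape(v)))
    for delta in history.times_before_dx:
        v_q = np.asarray(v) * np.exp(-delta / r)
        # underflow to zero volume is fine: the tumour was microscopic then
        d_q = np.cbrt(6.0 * v_q / np.pi)
        out = out * (1.0 - sensitivity(d_q, params))
    return out
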