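"""Tumour geometry, exponential growth, and the symptomatic-detection process.

A tumour is modelled as a sphere that starts from a single cell of diameter
``D_CELL`` (0.01 mm) and grows exponentially in volume: ``V(t | r) =
V_CELL * exp(t / r)`` where ``r`` is the woman-specific *inverse growth rate*
in years (volume doubles every ``r * ln 2`` years).  Tumours become detectable
once they exceed the diameter ``D0`` (0.5 mm); the time from one cell to
detectability is ``t0(r) = r * log(V0 / V_CELL)``.

Between-woman heterogeneity is captured by ``r ~ Gamma(tau1, rate=tau2)``.
Symptomatic detection is a non-homogeneous process with hazard proportional
to current volume, ``eta * V(t | r)`` (zero before ``t0``), which yields a
closed-form Pareto-type density for volume at symptomatic detection and a
Gamma posterior for ``r`` given the detected volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "D_CELL",
    "D0",
    "V_CELL",
    "V0",
    "GrowthParams",
    "sphere_volume",
    "sphere_diameter",
    "volume_at",
    "time_to_reach",
    "t0",
    "n_divisions",
    "division_rate",
    "inverse_growth_rate_pdf",
    "symptomatic_hazard",
    "vdet_pdf",
    "vdet_cdf",
    "r_given_vdet_pdf",
    "r_given_vdet_quadrature",
    "clamp_volume",
]

#: diameter of a single tumour cell, mm
D_CELL: float = 0.01
#: minimal detectable tumour diameter, mm
D0: float = 0.5

DAYS_PER_YEAR: float = 365.25


def sphere_volume(d):
    """Volume (mm^3) of a sphere of diameter ``d`` (mm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    return (np.pi / 6.0) * d**3


def sphere_diameter(v):
    """Diameter (mm) of a sphere of volume ``v`` (mm^3). Inverse of sphere_volume."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    return np.cbrt(6.0 * v / np.pi)


#: volume of a single cell, mm^3
V_CELL: float = float(sphere_volume(D_CELL))
#: minimal detectable volume, mm^3
V0: float = float(sphere_volume(D0))

#: log(V0 / V_CELL) = 3 log(D0 / D_CELL); t0(r) = r * LOG_V0_VCELL
LOG_V0_VCELL: float = 3.0 * math.log(D0 / D_CELL)


@dataclass(frozen=True)
class GrowthParams:
    """Growth-and-detection parameters.

    tau1, tau2
        Shape and rate (per year) of the Gamma distribution of inverse
        growth rates ``r``.
    eta
        Symptomatic-detection proportionality constant, per (mm^3 * year):
        the symptomatic hazard at time ``t`` is ``eta * V(t | r)``.
    """

    tau1: float
    tau2: float
    eta: float

    def __post_init__(self):
        if not (self.tau1 > 0 and self.tau2 > 0 and self.eta > 0):
            raise ValueError("tau1, tau2 and eta must all be strictly positive")


def volume_at(t, r):
    """Tumour volume (mm^3) at time ``t`` years after onset, given inverse rate ``r``."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return V_CELL * np.exp(t / r)


def time_to_reach(v, r):
    """Years for a tumour with inverse rate ``r`` to grow from one cell to volume ``v``."""
    v = np.asarray(v, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    if np.any(v < V_CELL * (1 - 1e-12)):
        raise ValueError("volume below a single cell")
    return r * np.log(np.maximum(v, V_CELL) / V_CELL)


def t0(r):
    """Time (years) from a single cell to the minimal detectable volume V0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    return r * LOG_V0_VCELL


def n_divisions(t, r):
    """Number of cell doublings by time ``t``: log2(V(t)/V_CELL) = t / (r ln 2)."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t / (r * math.log(2.0))


def division_rate(t, r):
    """Rate of doublings per year, 1 / (r ln 2); constant in t for exponential growth."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    return np.broadcast_to(1.0 / (r * math.log(2.0)), np.broadcast_shapes(t.shape, r.shape)).copy()


def inverse_growth_rate_pdf(r, params: GrowthParams):
    """Gamma(tau1, rate tau2) density of the inverse growth rate."""
    r = np.asarray(r, dtype=float)
    out = np.zeros(np.shape(r))
    ok = r >= 0
    rr = np.where(ok, r, 1.0)
    out = np.where(
        ok,
        np.exp(
            params.tau1 * math.log(params.tau2)
            - special.gammaln(params.tau1)
            + special.xlogy(params.tau1 - 1.0, rr)
            - params.tau2 * rr
        ),
        0.0,
    )
    return out


def symptomatic_hazard(t, r, eta):
    """Hazard of symptomatic detection: eta * V(t|r) once detectable, 0 before t0(r)."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    h = eta * volume_at(t, r)
    return np.where(t < t0(r), 0.0, h)


def vdet_pdf(v, params: GrowthParams):
    """Density of tumour volume at symptomatic detection (no screening).

    ``f(v) = eta * tau1 * tau2^tau1 / (tau2 + eta (v - V0))^(tau1 + 1)`` on
    ``v > V0``; a Pareto-type law obtained by marginalising the hazard model
    over the Gamma growth-rate distribution.
    """
    v = np.asarray(v, dtype=float)
    t1, t2, eta = params.tau1, params.tau2, params.eta
    dens = np.exp(
        math.log(eta)
        + math.log(t1)
        + t1 * math.log(t2)
        - (t1 + 1.0) * np.log(t2 + eta * np.maximum(v - V0, 0.0))
    )
    return np.where(v > V0, dens, 0.0)


def vdet_cdf(v, params: GrowthParams):
    """CDF of volume at symptomatic detection: 1 - [tau2/(tau2 + eta(v - V0))]^tau1."""
    v = np.asarray(v, dtype=float)
    t1, t2, eta = params.tau1, params.tau2, params.eta
    return np.where(v <= V0, 0.0, 1.0 - (t2 / (t2 + eta * np.maximum(v - V0, 0.0))) ** t1)


def _posterior_shape_rate(v, params: GrowthParams):
    v = float(v)
    if v < V0:
        raise ValueError("volume at detection must be at least V0")
    return params.tau1 + 1.0, params.tau2 + params.eta * (v - V0)


def r_given_vdet_pdf(r, v, params: GrowthParams):
    """Density of the inverse growth rate given symptomatic detection at volume ``v``.

    Gamma with shape tau1 + 1 and rate tau2 + eta (v - V0): conditioning on
    detection tilts the marginal Gamma towards slower tumours (larger r) by
    one extra shape unit, discounted by the detected volume.
    """
    shape, rate = _posterior_shape_rate(v, params)
    r = np.asarray(r, dtype=float)
    ok = r >= 0
    rr = np.where(ok, r, 1.0)
    return np.where(
        ok,
        np.exp(
            shape * math.log(rate)
            - special.gammaln(shape)
            + special.xlogy(shape - 1.0, rr)
            - rate * rr
        ),
        0.0,
    )


def r_given_vdet_quadrature(v, params: GrowthParams, n_nodes: int = 64):
    """Nodes and weights for integrals against the r | Vdet = v Gamma density.

    Generalized Gauss-Laguerre quadrature with alpha = shape - 1, nodes scaled
    by the rate: ``sum_i w_i g(r_i)`` equals ``E[g(R) | Vdet = v]`` exactly for
    polynomials up to degree 2 n_nodes - 1.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 quadrature nodes")
    shape, rate = _posterior_shape_rate(v, params)
    x, w = special.roots_genlaguerre(n_nodes, shape - 1.0)
    nodes = x / rate
    weights = w / math.gamma(shape)
    return nodes, weights


def gamma_quadrature(shape: float, n_nodes: int = 64):
    """Gauss-Laguerre nodes/weights for a unit-rate Gamma(shape) expectation.

    Returned nodes are on the unit-rate scale; divide by a rate to rescale.
    Weights sum to 1 up to roundoff.
    """
    x, w = special.roots_genlaguerre(n_nodes, shape - 1.0)
    return x, w / math.gamma(shape)


def clamp_volume(v):
    """Clamp volumes marginally below V0 (recording artefacts) up to the support.

    Raises for volumes below V0 by more than ~rounding; warns and clamps
    otherwise so that records with a recorded diameter of exactly 0.5 mm are
    kept instead of dropped.
    """
    v = np.asarray(v, dtype=float)
    lo = V0 * (1.0 + 1e-12)
    bad = v < lo
    if np.any(bad):
        if np.any(v < V0 * (1.0 - 1e-9)):
            raise ValueError("volume below the minimal detectable volume V0")
        warnings.warn("volume at or marginally below V0 clamped to the support boundary")
        v = np.where(bad, lo, v)
    return v
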