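"""Time from primary diagnosis to detection of the first distant metastasis.

Distant seeds arise from the same division-driven non-homogeneous Poisson
mechanism as nodal seeds, with its own rate ``sigma`` and instability exponent
``k_w``.  Seeding stops at diagnosis of the primary; each seed becomes a
detected distant metastasis exactly ``t0(r)`` years after it was shed (the
woman-specific time for one cell to become detectable).  With a
Gamma(omega1, omega2) frailty on ``sigma``, the time ``W`` from diagnosis to
first detected metastasis (given volume ``v`` at diagnosis and inverse rate
``r``) has closed-form density and survival:

* mass at ``W <= 0``: metastasis already detectable at diagnosis,
* an absolutely continuous part on ``0 < w <= t0(r)``,
* a plateau beyond ``t0(r)``: seeds shed before the tumour itself was
  detectable can no longer surface, so the survival flattens at the
  *cure fraction* ``[omega2 / (omega2 + log(v / V_CELL)^(k_w+1))]^omega1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LOG_V0_VCELL, V0, V_CELL

__all__ = [
    "DistantParams",
    "w_support_max",
    "w_pdf",
    "w_survival",
    "w_cdf",
    "prob_w_le0",
    "cure_fraction",
    "discretise_w_margin",
    "w_quantile",
]


@dataclass(frozen=True)
class DistantParams:
    """Frailty shape/inverse-scale of the distant seeding rate and exponent k_w."""

    omega1: float
    omega2: float
    k_w: float = 4.0

    def __post_init__(self):
        if not (self.omega1 > 0 and self.omega2 > 0):
            raise ValueError("omega1 and omega2 must be strictly positive")
        if self.k_w < -1:
            raise ValueError("k_w must be >= -1")


def w_support_max(r):
    """Upper end of the continuous support of W: t0(r) = r log(V0 / V_CELL).

    A metastasis detected at diagnosis + w was seeded at w - t0(r) <= 0, so no
    detection can occur later than t0(r) after diagnosis.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate r must be positive")
    return r * LOG_V0_VCELL


def _check_v(v):
    v = np.asarray(v, dtype=float)
    if np.any(v < V0 * (1 - 1e-12)):
        raise ValueError("volume at diagnosis must be at least V0")
    return v


def w_pdf(w, v, r, params: DistantParams):
    """Density of W on (0, t0(r)]; zero outside the support."""
    v = _check_v(v)
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    k, o1, o2 = params.k_w, params.omega1, params.omega2
    a = np.log(v / V0)
    x = w / r + a
    dens = (
        (k + 1.0)
        / r
        * x**k
        * o1
        * o2**o1
        / (o2 + x ** (k + 1.0)) ** (o1 + 1.0)
    )
    inside = (w >= 0) & (w <= w_support_max(r))
    return np.where(inside, dens, 0.0)


def w_survival(w, v, r, params: DistantParams):
    """P(W > w | V=v, R=r); flattens at the cure fraction beyond t0(r)."""
    v = _check_v(v)
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    k, o1, o2 = params.k_w, params.omega1, params.omega2
    a = np.log(v / V0)
    x = np.minimum(np.maximum(w, 0.0) / r + a, np.log(v / V_CELL))
    return (o2 / (o2 + x ** (k + 1.0))) ** o1


def w_cdf(w, v, r, params: DistantParams):
    """P(W <= w | V=v, R=r) = 1 - w_survival; includes the at-diagnosis mass at w=0."""
    return 1.0 - w_survival(w, v, r, params)


def prob_w_le0(v, params: DistantParams):
    """Probability of detectable distant metastasis already at diagnosis (r-free)."""
    v = _check_v(v)
    k, o1, o2 = params.k_w, params.omega1, params.omega2
    a = np.log(v / V0)
    return 1.0 - (o2 / (o2 + a ** (k + 1.0))) ** o1


def cure_fraction(v, params: DistantParams):
    """Probability of never being diagnosed with distant metastasis, given volume v.

    The plateau of w_survival: seeds could only be shed while the primary was
    in place, so survival beyond t0(r) cannot fall further.  Depends on r only
    through the (r-free) total log-growth log(v / V_CELL).
    """
    v = np.asarray(v, dtype=float)
    k, o1, o2 = params.k_w, params.omega1, params.omega2
    b = np.log(v / V_CELL)
    return (o2 / (o2 + b ** (k + 1.0))) ** o1


def discretise_w_margin(v, r, params: DistantParams, grid_max: int):
    """F_W at integer years 0..grid_max (year bin w holds mass on (w-1, w]).

    ``F_W(0)`` is the left-censored at-diagnosis mass; the vector plateaus at
    ``1 - cure_fraction(v)`` once the grid passes t0(r).  Sub-distribution:
    the cure mass is never spread over the grid.
    """
    if grid_max < 1:
        raise ValueError("grid_max must be >= 1")
    w = np.arange(grid_max + 1, dtype=float)
    return w_cdf(w, v, r, params)


def w_quantile(u, v, r, params: DistantParams):
    """Continuous inverse of w_cdf for u in (F_W(0), 1 - cure_fraction).

    Returns +inf where u exceeds the total non-cure mass (never diagnosed) and
    0 where u falls in the at-diagnosis mass.
    """
    v = _check_v(v)
    u = np.asarray(u, dtype=float)
    r = np.asarray(r, dtype=float)
    k, o1, o2 = params.k_w, params.omega1, params.omega2
    a = np.log(v / V0)
    q = 1.0 - u
    with np.errstate(over="ignore"):
        x = (o2 * (q ** (-1.0 / o1) - 1.0)) ** (1.0 / (k + 1.0))
    w = r * (x - a)
    w = np.where(u <= prob_w_le0(v, params), 0.0, w)
    return np.where(u > 1.0 - cure_fraction(v, params), np.inf, w)
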