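"""Bivariate Archimedean copulas with discretised margins.

The joint law of the node count ``N`` and the (discretised) time to distant
metastasis ``W`` is built by plugging their conditional CDFs into a bivariate
copula ``C(u1, u2; theta)``.  The families provided — Ali-Mikhail-Haq (amh),
Clayton, Frank, Gumbel, Joe and the product (independence) copula — each
carry a single association parameter ``theta`` mapping onto a family-specific
Kendall's tau range.  Because the margins are discrete, all probabilities are
rectangle differences of ``C`` over the margins' ranges; helpers here compute
the event / left-censored / right-censored cells used by the likelihood, plus
conditional-inversion sampling for the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import elementwise

__all__ = [
    "CopulaSpec",
    "FAMILIES",
    "copula_cdf",
    "kendall_tau",
    "joint_event_pmf",
    "joint_left_pmf",
    "joint_right_prob",
    "sample_copula",
]

FAMILIES = ("frank", "clayton", "amh", "gumbel", "joe", "product")

#: below this |theta|, frank/clayton/amh evaluate their independence limit
_THETA_TINY = 1e-6
_UEPS = 1e-12


@dataclass(frozen=True)
class CopulaSpec:
    """Copula family plus association parameter (ignored for ``product``)."""

    family: str
    theta: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}")
        th = self.theta
        if self.family == "frank" and th == 0.0:
            # treated as the product limit rather than an error
            pass
        elif self.family == "clayton" and (th < -1.0):
            raise ValueError("clayton requires theta >= -1")
        elif self.family == "amh" and not (-1.0 <= th <= 1.0):
            raise ValueError("amh requires theta in [-1, 1]")
        elif self.family in ("gumbel", "joe") and th < 1.0:
            raise ValueError(f"{self.family} requires theta >= 1")


def _clip(u):
    return np.clip(np.asarray(u, dtype=float), _UEPS, 1.0 - _UEPS)


def copula_cdf(u1, u2, spec: CopulaSpec):
    """C(u1, u2; family, theta).  Boundary-exact: C(u,1)=u, C(u,0)=0."""
    u1a = np.asarray(u1, dtype=float)
    u2a = np.asarray(u2, dtype=float)
    u = _clip(u1a)
    v = _clip(u2a)
    th = spec.theta
    fam = spec.family
    if fam == "product" or (fam in ("frank", "clayton", "amh") and abs(th) < _THETA_TINY):
        c = u * v
    elif fam == "frank":
        c = -np.log1p(np.expm1(-th * u) * np.expm1(-th * v) / np.expm1(-th)) / th
    elif fam == "clayton":
        c = np.maximum(u ** (-th) + v ** (-th) - 1.0, 0.0) ** (-1.0 / th)
    elif fam == "amh":
        c = u * v / (1.0 - th * (1.0 - u) * (1.0 - v))
    elif fam == "gumbel":
        c = np.exp(-(((-np.log(u)) ** th + (-np.log(v)) ** th) ** (1.0 / th)))
    elif fam == "joe":
        a = (1.0 - u) ** th
        b = (1.0 - v) ** th
        c = 1.0 - (a + b - a * b) ** (1.0 / th)
    # restore exact boundaries (clipping perturbs them by ~1e-12)
    c = np.where(u1a <= 0.0, 0.0, np.where(u1a >= 1.0, u2a, c))
    c = np.where(u2a <= 0.0, 0.0, np.where(u2a >= 1.0, np.minimum(u1a, 1.0), c))
    return np.clip(c, 0.0, 1.0)


def _debye1(theta: float) -> float:
    """Debye function D1(theta) = (1/theta) * int_0^theta t / (e^t - 1) dt."""

    def integrand(t):
        return t / math.expm1(t) if t != 0.0 else 1.0

    val, _ = integrate.quad(integrand, 0.0, theta)
    return val / theta


def kendall_tau(spec: CopulaSpec) -> float:
    """Kendall's tau implied by the copula family at its theta."""
    th = spec.theta
    fam = spec.family
    if fam == "product":
        return 0.0
    if fam in ("frank", "clayton", "amh") and abs(th) < _THETA_TINY:
        return 0.0
    if fam == "frank":
        return 1.0 + 4.0 * (_debye1(th) - 1.0) / th
    if fam == "clayton":
        return th / (th + 2.0)
    if fam == "gumbel":
        return 1.0 - 1.0 / th
    if fam == "amh":
        if th == 1.0:
            return 1.0 / 3.0
        return 1.0 - 2.0 * (th + (1.0 - th) ** 2 * math.log1p(-th)) / (3.0 * th**2)
    if fam == "joe":
        # generic Archimedean identity tau = 1 + 4 int_0^1 phi(t)/phi'(t) dt
        def ratio(t):
            omt = 1.0 - t
            u = omt**th
            if u >= 1.0:
                return 0.0
            return math.log1p(-u) * (1.0 - u) / (th * omt ** (th - 1.0))

        val, _ = integrate.quad(ratio, 0.0, 1.0, points=[0.0, 1.0])
        return 1.0 + 4.0 * val
    raise AssertionError(fam)


def joint_event_pmf(n, w, F_N, F_W, spec: CopulaSpec):
    """P(N = n, W = w) for an observed event year w >= 1.

    ``F_N`` and ``F_W`` are callables (or dict-like via ``__call__``) returning
    the discrete marginal CDFs at integer arguments; the cell is the copula
    rectangle over [F_N(n-1), F_N(n)] x [F_W(w-1), F_W(w)].
    """
    n = int(n)
    w = int(w)
    if w < 1:
        raise ValueError("event year must be >= 1")
    if n < 0:
        raise ValueError("node count must be >= 0")
    fn_hi = F_N(n)
    fw_hi, fw_lo = F_W(w), F_W(w - 1)
    if fw_lo > fw_hi + 1e-12:
        raise ValueError("F_W must be non-decreasing")
    hi = copula_cdf(fn_hi, fw_hi, spec) - copula_cdf(fn_hi, fw_lo, spec)
    if n == 0:
        return float(np.maximum(hi, 0.0))
    fn_lo = F_N(n - 1)
    if fn_lo > fn_hi + 1e-12:
        raise ValueError("F_N must be non-decreasing")
    lo = copula_cdf(fn_lo, fw_hi, spec) - copula_cdf(fn_lo, fw_lo, spec)
    return float(np.maximum(hi - lo, 0.0))


def joint_left_pmf(n, F_N, F_W0, spec: CopulaSpec):
    """P(N = n, W <= 0): left-censored cell; r-free as both arguments are."""
    n = int(n)
    if n < 0:
        raise ValueError("node count must be >= 0")
    if not 0.0 <= F_W0 <= 1.0:
        raise ValueError("F_W0 must be a probability")
    hi = copula_cdf(F_N(n), F_W0, spec)
    if n == 0:
        return float(hi)
    return float(np.maximum(hi - copula_cdf(F_N(n - 1), F_W0, spec), 0.0))


def joint_right_prob(n, w, F_N, F_W, spec: CopulaSpec):
    """P(N = n, W > w): right-censored cell at follow-up year w >= 0."""
    n = int(n)
    w = int(w)
    if n < 0 or w < 0:
        raise ValueError("need n >= 0 and w >= 0")
    fn_hi = F_N(n)
    fw = F_W(w)
    if n == 0:
        return float(np.maximum(fn_hi - copula_cdf(fn_hi, fw, spec), 0.0))
    fn_lo = F_N(n - 1)
    val = (fn_hi - fn_lo) - (copula_cdf(fn_hi, fw, spec) - copula_cdf(fn_lo, fw, spec))
    return float(np.maximum(val, 0.0))


# --- rectangle cells on arrays (used by the vectorised likelihood) ---------


def rect_event(fn_lo, fn_hi, fw_lo, fw_hi, spec: CopulaSpec):
    """Vectorised rectangle probability over [fn_lo, fn_hi] x [fw_lo, fw_hi]."""
    val = (
        copula_cdf(fn_hi, fw_hi, spec)
        - copula_cdf(fn_lo, fw_hi, spec)
        - copula_cdf(fn_hi, fw_lo, spec)
        + copula_cdf(fn_lo, fw_lo, spec)
    )
    return np.maximum(val, 0.0)


def rect_right(fn_lo, fn_hi, fw, spec: CopulaSpec):
    """Vectorised P(F_N-cell, W > w) = (fn_hi - fn_lo) - C-difference at fw."""
    val = (fn_hi - fn_lo) - (copula_cdf(fn_hi, fw, spec) - copula_cdf(fn_lo, fw, spec))
    return np.maximum(val, 0.0)


# --- sampling ---------------------------------------------------------------


def _conditional_cdf(u2, u1, spec: CopulaSpec):
    """h(u2 | u1) = dC/du1, the conditional CDF of U2 given U1 = u1."""
    th = spec.theta
    fam = spec.family
    u = _clip(u1)
    v = _clip(u2)
    if fam == "product" or (fam in ("frank", "clayton", "amh") and abs(th) < _THETA_TINY):
        return v
    if fam == "frank":
        num = np.exp(-th * u) * np.expm1(-th * v)
        den = np.expm1(-th) + np.expm1(-th * u) * np.expm1(-th * v)
        return num / den
    if fam == "clayton":
        s = np.maximum(u ** (-th) + v ** (-th) - 1.0, 0.0)
        return np.where(s > 0.0, u ** (-th - 1.0) * s ** (-1.0 / th - 1.0), 0.0)
    if fam == "amh":
        d = 1.0 - th * (1.0 - u) * (1.0 - v)
        return v * (d - th * u * (1.0 - v)) / d**2
    if fam == "gumbel":
        lu = -np.log(u)
        lv = -np.log(v)
        s = lu**th + lv**th
        c = np.exp(-(s ** (1.0 / th)))
        return c * s ** (1.0 / th - 1.0) * lu ** (th - 1.0) / u
    if fam == "joe":
        a = (1.0 - u) ** th
        b = (1.0 - v) ** th
        s = a + b - a * b
        return (1.0 - u) ** (th - 1.0) * (1.0 - b) * s ** (1.0 / th - 1.0)
    raise AssertionError(fam)


def conditional_quantile(p, u1, spec: CopulaSpec):
    """Invert h(. | u1) at p — the conditional-distribution sampling step."""
    p = np.asarray(p, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    fam, th = spec.family, spec.theta
    if fam == "product" or (fam in ("frank", "clayton", "amh") and abs(th) < _THETA_TINY):
        return p
    if fam == "frank":
        u = _clip(u1)
        pe = _clip(p)
        x = pe * np.expm1(-th) / (np.exp(-th * u) * (1.0 - pe) + pe)
        return np.clip(-np.log1p(x) / th, 0.0, 1.0)
    if fam == "clayton":
        u = _clip(u1)
        pe = _clip(p)
        if th <= -1.0 + 1e-9:
            # lower Frechet bound: U2 = 1 - U1 almost surely
            return 1.0 - u
        v = (1.0 + u ** (-th) * (pe ** (-th / (1.0 + th)) - 1.0)) ** (-1.0 / th)
        return np.clip(v, 0.0, 1.0)

    pe = _clip(p)
    shape = np.broadcast_shapes(pe.shape, u1.shape)
    pe_b = np.broadcast_to(pe, shape)
    u1_b = np.broadcast_to(np.asarray(u1, dtype=float), shape)

    def f(v, uu, pp):
        return _conditional_cdf(v, uu, spec) - pp

    lo = np.full(shape, _UEPS)
    hi = np.full(shape, 1.0 - _UEPS)
    res = elementwise.find_root(f, (lo, hi), args=(u1_b, pe_b))
    return np.clip(res.x, 0.0, 1.0)


def sample_copula(spec: CopulaSpec, n_draws: int, seed=None):
    """Draw (u1, u2) pairs via the conditional-distribution method."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    u1 = rng.uniform(size=n_draws)
    p = rng.uniform(size=n_draws)
    u2 = conditional_quantile(p, u1, spec)
    return u1, np.asarray(u2, dtype=float)
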