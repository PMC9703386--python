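"""Lymph-node seeding and the negative-binomial law of affected nodes.

Detectable nodal metastases are seeded by a non-homogeneous Poisson process
whose intensity is proportional to ``D(t, r)^k_n * D'(t, r)`` — the number of
cell divisions so far raised to a *genomic instability* exponent, times the
division rate.  Integrating from detectability gives the cumulative intensity
``Lambda = s * [log(V / V0)]^(k_n + 1)`` which depends on the tumour only
through its current volume.  A Gamma(gamma1, gamma2) frailty on the per-woman
seeding rate ``s`` then mixes the Poisson count into a negative binomial with
size ``gamma1`` and success probability ``gamma2 / (L + gamma2)``, where
``L = [log(v / V0)]^(k_n + 1)``.  The node count is conditionally independent
of the growth rate given volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import V0, t0, volume_at

__all__ = [
    "NodalParams",
    "NodalDistribution",
    "seeding_intensity",
    "cumulative_seeding",
    "nb_parameters",
    "node_pmf",
    "node_cdf",
    "node_quantile",
]

#: support cap when summing the node distribution; observed counts are far smaller
N_MAX: int = 1000


@dataclass(frozen=True)
class NodalParams:
    """Frailty shape/inverse-scale for the nodal seeding rate and exponent k_n."""

    gamma1: float
    gamma2: float
    k_n: float = 4.0

    def __post_init__(self):
        if not (self.gamma1 > 0 and self.gamma2 > 0):
            raise ValueError("gamma1 and gamma2 must be strictly positive")
        if self.k_n < -1:
            raise ValueError("k_n must be >= -1")


@dataclass(frozen=True)
class NodalDistribution:
    """Negative-binomial size/probability implied by a tumour volume."""

    l: float
    p: float
    L: float


def seeding_intensity(t, r, s_star, k_n):
    """NHPP intensity s* D(t,r)^k_n D'(t,r) for nodal seeding (0 before t >= 0)."""
    if k_n < -1:
        raise ValueError("k_n must be >= -1")
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    ln2 = math.log(2.0)
    d = t / (r * ln2)
    return s_star * d**k_n / (r * ln2)


def s_from_s_star(s_star, k_n):
    """Reparameterised rate s = s* / [(k_n+1) (ln 2)^(k_n+1)]."""
    return s_star / ((k_n + 1.0) * math.log(2.0) ** (k_n + 1.0))


def cumulative_seeding(t, r, s, k_n):
    """Expected detectable nodal seeds by time t: s [log(V(t)/V0)]^(k_n+1), 0 before t0."""
    if k_n < -1:
        raise ValueError("k_n must be >= -1")
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    lam = s * np.maximum(np.log(volume_at(t, r) / V0), 0.0) ** (k_n + 1.0)
    return np.where(t < t0(r), 0.0, lam)


def log_volume_power(v, k):
    """L = [log(v / V0)]^(k+1), the volume-dependent exposure of the seeding process."""
    v = np.asarray(v, dtype=float)
    if np.any(v < V0 * (1 - 1e-12)):
        raise ValueError("volume must be at least V0")
    return np.maximum(np.log(v / V0), 0.0) ** (k + 1.0)


def nb_parameters(v, params: NodalParams) -> NodalDistribution:
    """Negative-binomial (size, probability) of the node count at volume v."""
    L = float(log_volume_power(v, params.k_n))
    p = params.gamma2 / (L + params.gamma2)
    return NodalDistribution(l=params.gamma1, p=p, L=L)


def _nb(v, params: NodalParams):
    L = log_volume_power(v, params.k_n)
    p = params.gamma2 / (L + params.gamma2)
    return params.gamma1, p


def node_pmf(n, v, params: NodalParams):
    """P(N = n | V = v): negative binomial with size gamma1, prob gamma2/(L+gamma2)."""
    n = np.asarray(n)
    if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer) and np.any(n != np.floor(n)):
        raise ValueError("node count must be a non-negative integer")
    size, p = _nb(v, params)
    return stats.nbinom.pmf(n, size, p)


def node_cdf(n, v, params: NodalParams):
    """P(N <= n | V = v)."""
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("node count must be a non-negative integer")
    size, p = _nb(v, params)
    return stats.nbinom.cdf(n, size, p)


def node_quantile(u, v, params: NodalParams):
    """Generalised inverse of node_cdf: smallest n with F_N(n) >= u."""
    size, p = _nb(v, params)
    return stats.nbinom.ppf(np.asarray(u, dtype=float), size, p).astype(int)
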