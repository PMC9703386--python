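"""Cohort log-likelihood under the joint copula natural-history model.

Each woman contributes the density of her tumour volume at detection times
the copula cell probability of her observed (node count, metastasis-time)
pair, integrated over the conditional distribution of her inverse growth
rate given the detected volume.  Screen-detected women additionally
contribute the screening sensitivity at detection, and any woman with prior
negative screens contributes the backward-projected negative-screen product
inside the r-integral.  The metastasis-time margin is discretised to whole
years: an "event" in year ``w`` is the rectangle over (w-1, w], "left" is
mass already at diagnosis (r-free), "right" is the upper tail past the
follow-up year.

The heavy lifting is vectorised across (records x quadrature nodes); the
per-record functions are thin wrappers over the same code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special, stats

from . import copulas
from .cohort import PatientRecord, frame_to_records
from .geometry import V0, V_CELL, sphere_volume
from .params import ModelParams
from .screening import sensitivity

__all__ = [
    "LikelihoodOptions",
    "loglik_unscreened",
    "loglik_screened",
    "total_negloglik",
    "cohort_logliks",
]


@dataclass(frozen=True)
class LikelihoodOptions:
    """Numerical controls for the likelihood.

    n_quad_nodes
        Gauss-Laguerre nodes for the inverse-growth-rate integral.
    grid_max_years
        Largest follow-up year the discretised metastasis margin must cover;
        only validated against the data (the cells themselves are local).
    log_floor
        Smallest admissible cell probability before taking logs; floored
        contributions are counted, not raised.
    """

    n_quad_nodes: int = 64
    grid_max_years: int = 30
    log_floor: float = 1e-300

    def __post_init__(self):
        if self.n_quad_nodes < 8:
            raise ValueError("need at least 8 quadrature nodes")
        if self.grid_max_years < 1:
            raise ValueError("grid_max_years must be >= 1")


class CohortArrays:
    """Columnar view of a cohort used by the vectorised likelihood."""

    def __init__(self, dataset):
        if isinstance(dataset, pd.DataFrame):
            records = frame_to_records(dataset)
        elif isinstance(dataset, PatientRecord):
            records = [dataset]
        else:
            records = list(dataset)
        if not records:
            raise ValueError("dataset is empty")
        self.records = records
        self.n_rec = len(records)
        self.v = np.array([sphere_volume(rec.diameter_mm) for rec in records])
        self.d = np.array([rec.diameter_mm for rec in records])
        self.n = np.array([rec.n_nodes for rec in records], dtype=int)
        self.w = np.array([rec.w_years for rec in records], dtype=int)
        self.is_event = np.array([rec.status == "event" for rec in records])
        self.is_left = np.array([rec.status == "left" for rec in records])
        self.is_right = np.array([rec.status == "right" for rec in records])
        self.is_screen = np.array([rec.mode == "screen" for rec in records])
        qmax = max((len(rec.screens) for rec in records), default=0)
        self.screen_offsets = np.full((self.n_rec, qmax), np.nan)
        for i, rec in enumerate(records):
            for q, delta in enumerate(rec.screens.times_before_dx):
                self.screen_offsets[i, q] = delta
        self.any_screening = bool(self.is_screen.any() or qmax > 0)


def _prepare(dataset) -> CohortArrays:
    return dataset if isinstance(dataset, CohortArrays) else CohortArrays(dataset)


def _fw_discrete(w_over_r_plus_a, b, params: ModelParams):
    """Discretised metastasis-time CDF from the clipped argument min(w/r + a, b)."""
    k, o1, o2 = params.distant.k_w, params.distant.omega1, params.distant.omega2
    x = np.minimum(w_over_r_plus_a, b)
    return 1.0 - (o2 / (o2 + x ** (k + 1.0))) ** o1


@lru_cache(maxsize=8)
def _leggauss(n):
    return np.polynomial.legendre.leggauss(n)


@lru_cache(maxsize=8)
def _laguerre(n):
    return special.roots_laguerre(n)


def _r_quadrature(rate, shape, c_lo, c_hi, n_nodes):
    """Piecewise quadrature of the Gamma(shape, rate) r-mixture per record.

    The discretised metastasis-time CDF at year w has a derivative kink in r
    where ``w / r`` crosses the support boundary (the survival plateau), i.e.
    at ``r = w / log(V0 / V_CELL)``; integrating across it with a single
    Gauss rule converges erratically.  Each record therefore gets a finite
    Gauss-Legendre segment on (c_lo, c_hi) plus a Gauss-Laguerre tail on
    (c_hi, inf), with the Gamma density folded into the weights.  Rows with
    ``c_hi = 0`` collapse to the plain tail rule on (0, inf).

    Returns (r, weights), each of shape (n_records, n_nodes).
    """
    rate = np.asarray(rate, dtype=float)
    c_lo = np.asarray(c_lo, dtype=float)
    c_hi = np.asarray(c_hi, dtype=float)
    n_f = n_nodes // 4
    n_m = n_nodes // 4
    n_t = n_nodes - n_f - n_m
    xg, wg = _leggauss(n_f)
    xm, wm = _leggauss(n_m)
    xl, wl = _laguerre(n_t)
    lognorm = special.gammaln(shape)

    def _pdf_weights(r_seg, base_w, ok):
        r_safe = np.where(ok, r_seg, 1.0)
        log_pdf = (
            shape * np.log(rate)[:, None]
            + special.xlogy(shape - 1.0, r_safe)
            - rate[:, None] * r_safe
            - lognorm
        )
        return np.where(ok, base_w * np.exp(log_pdf), 0.0), r_safe

    # finite segment (c_lo, c_hi); the u^2 map grades nodes towards c_lo,
    # where the year-1 event cell has a fractional-power singularity in r
    width = (c_hi - c_lo)[:, None]
    u = ((xg + 1.0) / 2.0)[None, :]
    r_f = c_lo[:, None] + width * u**2
    wt_f, r_f = _pdf_weights(r_f, wg[None, :] * width * u, (width > 0) & (r_f > 0))
    # middle segment (c_hi, 4 c_hi): the cell still varies steeply just past
    # the kink, too steeply for the Laguerre tail rule alone
    c2 = 4.0 * c_hi
    half_m = (c2 - c_hi)[:, None] / 2.0
    r_m = c_hi[:, None] + half_m * (xm[None, :] + 1.0)
    wt_m, r_m = _pdf_weights(r_m, wm[None, :] * half_m, half_m > 0)
    # Laguerre tail on (4 c_hi, inf) against weight e^{-x}
    rc = rate[:, None] * c2[:, None]
    r_t = c2[:, None] + xl[None, :] / rate[:, None]
    wt_t = np.exp(
        special.xlogy(shape - 1.0, rc + xl[None, :]) - rc - lognorm + np.log(wl)[None, :]
    )
    r = np.concatenate([r_f, r_m, r_t], axis=1)
    wts = np.concatenate([wt_f, wt_m, wt_t], axis=1)
    # renormalise each row to the exact Gamma mass beyond c_lo
    target = special.gammaincc(shape, rate * c_lo)
    total = wts.sum(axis=1)
    wts = wts * np.where(total > 0, target / np.where(total > 0, total, 1.0), 1.0)[:, None]
    return r, wts


def cohort_logliks(dataset, params: ModelParams, options: LikelihoodOptions | None = None,
                   screened: bool | None = None):
    """Per-record log-likelihood contributions (natural log).

    ``screened=None`` infers the regime from the data (any screen-detected
    record or any recorded negative screen).  Returns ``(logliks, n_floored)``.
    """
    data = _prepare(dataset)
    options = options or LikelihoodOptions()
    if screened is None:
        screened = data.any_screening
    if int(data.w.max(initial=0)) > options.grid_max_years:
        raise ValueError("grid_max_years smaller than the largest observed w")

    g = params.growth
    nod = params.nodal
    dist = params.distant
    spec = params.copula

    v = data.v  # (n,)
    a = np.log(v / V0)
    b = np.log(v / V_CELL)

    # size-at-detection density (log)
    rate = g.tau2 + g.eta * (v - V0)
    log_fv = math.log(g.eta) + math.log(g.tau1) + g.tau1 * math.log(g.tau2) - (g.tau1 + 1.0) * np.log(rate)

    # node-margin cells (r-free)
    L = a ** (nod.k_n + 1.0)
    p = nod.gamma2 / (L + nod.gamma2)
    fn_hi = stats.nbinom.cdf(data.n, nod.gamma1, p)
    fn_lo = np.where(data.n > 0, stats.nbinom.cdf(data.n - 1, nod.gamma1, p), 0.0)

    # quadrature over r | Vdet = v: Gamma(tau1 + 1, rate), split at the
    # plateau kink r = w / log(V0 / V_CELL) of the year-w metastasis cell
    K = math.log(V0 / V_CELL)
    c_hi = np.where(data.is_left, 0.0, data.w / K)
    c_lo = np.where(data.is_event, np.maximum(data.w - 1, 0) / K, 0.0)
    r, wq2 = _r_quadrature(rate, g.tau1 + 1.0, c_lo, c_hi, options.n_quad_nodes)

    # negative-screen product over the quadrature nodes
    sp = np.ones_like(r)
    if screened and data.screen_offsets.shape[1] > 0:
        sens_p = params.screening
        for q in range(data.screen_offsets.shape[1]):
            delta = data.screen_offsets[:, q]
            has = np.isfinite(delta)
            if not has.any():
                continue
            v_q = v[:, None] * np.exp(-np.where(has, delta, 0.0)[:, None] / r)
            d_q = np.cbrt(6.0 * v_q / np.pi)
            term = 1.0 - np.asarray(sensitivity(d_q, sens_p))
            sp = np.where(has[:, None], sp * term, sp)

    # metastasis-margin CDF at the needed integer years, per quadrature node;
    # rectangles are computed only on the rows whose status needs them
    integ = np.einsum("ij,ij->i", sp, wq2)  # left-censored rows: screen product alone
    for idx, kind in ((np.flatnonzero(data.is_event), "event"),
                      (np.flatnonzero(data.is_right), "right")):
        if idx.size == 0:
            continue
        w_arr = data.w[idx, None].astype(float)
        r_s = r[idx]
        a_s = a[idx, None]
        b_s = b[idx, None]
        fw_hi = _fw_discrete(w_arr / r_s + a_s, b_s, params)
        fn_lo2 = np.broadcast_to(fn_lo[idx, None], r_s.shape)
        fn_hi2 = np.broadcast_to(fn_hi[idx, None], r_s.shape)
        if kind == "event":
            fw_lo = _fw_discrete(np.maximum(w_arr - 1.0, 0.0) / r_s + a_s, b_s, params)
            cell = copulas.rect_event(fn_lo2, fn_hi2, fw_lo, fw_hi, spec)
        else:
            cell = copulas.rect_right(fn_lo2, fn_hi2, fw_hi, spec)
        integ[idx] = np.einsum("ij,ij,ij->i", sp[idx], cell, wq2[idx])

    # left-censored cells are r-free; multiply outside the integral
    if data.is_left.any():
        fw0 = 1.0 - (dist.omega2 / (dist.omega2 + a ** (dist.k_w + 1.0))) ** dist.omega1
        left_cell = np.asarray(copulas.copula_cdf(fn_hi, fw0, spec)) - np.where(
            data.n > 0, np.asarray(copulas.copula_cdf(fn_lo, fw0, spec)), 0.0
        )
        integ = np.where(data.is_left, integ * np.maximum(left_cell, 0.0), integ)

    floored = integ < options.log_floor
    ll = log_fv + np.log(np.maximum(integ, options.log_floor))

    if screened:
        sens_det = np.asarray(sensitivity(data.d, params.screening))
        ll = ll + np.where(data.is_screen, np.log(np.maximum(sens_det, options.log_floor)), 0.0)

    return ll, int(np.count_nonzero(floored))


def loglik_unscreened(record: PatientRecord, params: ModelParams,
                      options: LikelihoodOptions | None = None) -> float:
    """Log-likelihood of one record under the no-screening regime."""
    ll, _ = cohort_logliks([record], params, options, screened=False)
    return float(ll[0])


def loglik_screened(record: PatientRecord, params: ModelParams,
                    options: LikelihoodOptions | None = None) -> float:
    """Log-likelihood of one record with detection mode and screen history."""
    ll, _ = cohort_logliks([record], params, options, screened=True)
    return float(ll[0])


def total_negloglik(dataset, params: ModelParams, options: LikelihoodOptions | None = None,
                    screened: bool | None = None) -> float:
    """Summed negative log-likelihood of a cohort."""
    ll, _ = cohort_logliks(dataset, params, options, screened=screened)
    return float(-np.sum(ll))
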