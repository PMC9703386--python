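"""Model-based predictions: metastasis risk at and after diagnosis, cure.

Given a fitted parameter set, a woman's tumour volume and node count at
diagnosis (and, for post-diagnosis survival, her mode of detection and
screening history) yield:

* the probability that distant metastasis was already detectable at
  diagnosis,
* the probability of ever being diagnosed with distant metastasis, whose
  complement is a conditional *cure* probability,
* distant-metastasis-free survival conditional on being metastasis-free at
  diagnosis,

plus cohort-level versions obtained by averaging the per-woman predictions
within node-count groups, with delta-method pointwise confidence intervals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import copulas
from .distant import cure_fraction, prob_w_le0
from .geometry import DAYS_PER_YEAR, V0, V_CELL, sphere_volume
from .inference import FitResult, delta_method_se, untransform_params
from .likelihood import CohortArrays, LikelihoodOptions, _fw_discrete
from .nodal import node_cdf, node_pmf
from .params import ModelParams
from .screening import ScreeningHistory, negative_screens_likelihood

__all__ = [
    "p_dm_at_diagnosis",
    "p_dm_ever",
    "cure",
    "dm_free_survival",
    "marginal_curves",
    "marginal_cure",
    "doubling_time_summary",
]


def _node_cells(n, v, params: ModelParams):
    n = np.asarray(n, dtype=int)
    fn_hi = np.asarray(node_cdf(n, v, params.nodal))
    fn_lo = np.where(n > 0, np.asarray(node_cdf(np.maximum(n - 1, 0), v, params.nodal)), 0.0)
    pmf = np.asarray(node_pmf(n, v, params.nodal))
    if np.any(pmf <= 0):
        raise ValueError("node pmf is zero at the requested count; prediction undefined")
    return fn_lo, fn_hi, pmf


def p_dm_at_diagnosis(n, v, params: ModelParams):
    """P(W <= 0 | N = n, V = v): metastasis already detectable at diagnosis (r-free)."""
    fn_lo, fn_hi, pmf = _node_cells(n, v, params)
    fw0 = np.asarray(prob_w_le0(v, params.distant))
    num = np.asarray(copulas.copula_cdf(fn_hi, fw0, params.copula)) - np.asarray(
        copulas.copula_cdf(fn_lo, fw0, params.copula)
    )
    out = np.clip(num / pmf, 0.0, 1.0)
    return out if out.shape else float(out)


def p_dm_ever(n, v, params: ModelParams):
    """P(ever diagnosed with distant metastasis | N = n, V = v).

    The metastasis-time margin is capped at its total non-cure mass
    ``1 - cure_fraction(v)`` (an r-free quantity), so this includes both
    detected-at-diagnosis and future metastases.
    """
    fn_lo, fn_hi, pmf = _node_cells(n, v, params)
    fw_inf = 1.0 - np.asarray(cure_fraction(v, params.distant))
    num = np.asarray(copulas.copula_cdf(fn_hi, fw_inf, params.copula)) - np.asarray(
        copulas.copula_cdf(fn_lo, fw_inf, params.copula)
    )
    out = np.clip(num / pmf, 0.0, 1.0)
    return out if out.shape else float(out)


def cure(n, v, params: ModelParams):
    """Conditional cure probability: 1 - p_dm_ever(n, v)."""
    return 1.0 - p_dm_ever(n, v, params)


def _right_integral(w_star, n, v, screens: ScreeningHistory, params: ModelParams,
                    n_nodes: int = 64):
    """int P(N = n, W > w*) x negative-screen product over r | Vdet = v."""
    from .likelihood import _r_quadrature

    g = params.growth
    rate = np.array([g.tau2 + g.eta * (v - V0)])
    c_hi = np.array([float(w_star) / math.log(V0 / V_CELL)])
    r, wq = _r_quadrature(rate, g.tau1 + 1.0, np.zeros(1), c_hi, n_nodes)
    r, wq = r[0], wq[0]
    fn_lo, fn_hi, _ = _node_cells(n, v, params)
    a = math.log(v / V0)
    b = math.log(v / V_CELL)
    fw = _fw_discrete(float(w_star) / r + a, b, params)
    cell = copulas.rect_right(float(fn_lo), float(fn_hi), fw, params.copula)
    sp = negative_screens_likelihood(screens, v, r, params.screening)
    return float(np.sum(wq * sp * cell))


def dm_free_survival(w_star, n, v, params: ModelParams, mode: str = "symptomatic",
                     screens: ScreeningHistory | None = None,
                     options: LikelihoodOptions | None = None):
    """P(W > w* | N = n, V = v, metastasis-free at diagnosis, screening history).

    A ratio of growth-rate-integrated right-tail probabilities at ``w*`` and
    at 0; any r-free factor (including the screen-detection sensitivity)
    cancels, so ``mode`` only matters through the recorded screens.
    """
    if w_star < 0 or int(w_star) != w_star:
        raise ValueError("w_star must be a non-negative integer year")
    screens = screens or ScreeningHistory(())
    options = options or LikelihoodOptions()
    den = _right_integral(0, n, v, screens, params, options.n_quad_nodes)
    if den <= 0:
        raise ValueError("P(W > 0, N = n) is zero; conditional survival undefined")
    if w_star == 0:
        return 1.0
    num = _right_integral(int(w_star), n, v, screens, params, options.n_quad_nodes)
    return float(min(max(num / den, 0.0), 1.0))


def _curve_matrix(data: CohortArrays, params: ModelParams, horizon: int, n_nodes: int):
    """Per-record conditional survival curves, vectorised over (record, node)."""
    from .likelihood import _r_quadrature
    from .screening import sensitivity

    g = params.growth
    rate = g.tau2 + g.eta * (data.v - V0)
    a = np.log(data.v / V0)[:, None]
    b = np.log(data.v / V_CELL)[:, None]
    fn_lo, fn_hi, _ = _node_cells(data.n, data.v, params)
    K = math.log(V0 / V_CELL)
    curves = np.empty((data.n_rec, horizon + 1))
    den = None
    for w in range(horizon + 1):
        r, wq = _r_quadrature(rate, g.tau1 + 1.0, np.zeros(data.n_rec),
                              np.full(data.n_rec, w / K), n_nodes)
        sp = np.ones_like(r)
        for q in range(data.screen_offsets.shape[1]):
            delta = data.screen_offsets[:, q]
            has = np.isfinite(delta)
            if not has.any():
                continue
            v_q = data.v[:, None] * np.exp(-np.where(has, delta, 0.0)[:, None] / r)
            d_q = np.cbrt(6.0 * v_q / np.pi)
            term = 1.0 - np.asarray(sensitivity(d_q, params.screening))
            sp = np.where(has[:, None], sp * term, sp)
        fw = _fw_discrete(float(w) / r + a, b, params)
        fn_lo2 = np.broadcast_to(fn_lo[:, None], r.shape)
        fn_hi2 = np.broadcast_to(fn_hi[:, None], r.shape)
        cell = copulas.rect_right(fn_lo2, fn_hi2, fw, params.copula)
        integ = np.einsum("ij,ij,ij->i", sp, cell, wq)
        if w == 0:
            den = np.maximum(integ, 1e-300)
        curves[:, w] = integ / den
    return np.clip(curves, 0.0, 1.0)


def _groups(data: CohortArrays, by):
    if by is None:
        by = {"0 nodes": [0], "1 node": [1], "2 nodes": [2]}
    return {name: np.isin(data.n, np.asarray(counts)) for name, counts in by.items()}


def marginal_curves(dataset, params: ModelParams, by=None, horizon: int = 10,
                    fit_result: FitResult | None = None,
                    options: LikelihoodOptions | None = None) -> pd.DataFrame:
    """Node-group-averaged metastasis-free survival curves with pointwise CIs.

    Averages each woman's conditional survival curve over the observed
    covariates within each node group; CIs (when ``fit_result`` carries a
    covariance) are delta-method on the group average.
    """
    import warnings as _warnings

    data = dataset if isinstance(dataset, CohortArrays) else CohortArrays(dataset)
    options = options or LikelihoodOptions()
    template = params
    rows = []
    groups = _groups(data, by)
    base = _curve_matrix(data, params, horizon, options.n_quad_nodes)
    for name, mask in groups.items():
        if not mask.any():
            _warnings.warn(f"node group {name!r} is empty; skipped")
            continue
        est = base[mask].mean(axis=0)
        for w in range(horizon + 1):
            lo = hi = np.nan
            if fit_result is not None and fit_result.vcov is not None:
                def fn(z, w=w, mask=mask):
                    x = fit_result.transformed_estimates.copy()
                    x[fit_result.free] = z
                    p = untransform_params(x, template)
                    return _curve_matrix(data, p, w if w > 0 else 1, options.n_quad_nodes)[mask, w].mean()

                se = delta_method_se(fn, fit_result)
                lo, hi = max(est[w] - 1.96 * se, 0.0), min(est[w] + 1.96 * se, 1.0)
            rows.append({"group": name, "w": w, "estimate": est[w], "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


def marginal_cure(dataset, params: ModelParams, by=None,
                  fit_result: FitResult | None = None) -> pd.DataFrame:
    """Node-group-averaged conditional cure probabilities (with delta-method CIs)."""
    import warnings as _warnings

    data = dataset if isinstance(dataset, CohortArrays) else CohortArrays(dataset)
    groups = _groups(data, by)
    cures = np.array([cure(int(n_i), float(v_i), params) for n_i, v_i in zip(data.n, data.v)])
    rows = []
    for name, mask in groups.items():
        if not mask.any():
            _warnings.warn(f"node group {name!r} is empty; skipped")
            continue
        est = float(cures[mask].mean())
        lo = hi = np.nan
        if fit_result is not None and fit_result.vcov is not None:
            def fn(z, mask=mask):
                x = fit_result.transformed_estimates.copy()
                x[fit_result.free] = z
                p = untransform_params(x, params)
                vals = [cure(int(n_i), float(v_i), p) for n_i, v_i in zip(data.n[mask], data.v[mask])]
                return float(np.mean(vals))

            se = delta_method_se(fn, fit_result)
            lo, hi = max(est - 1.96 * se, 0.0), min(est + 1.96 * se, 1.0)
        rows.append({"group": name, "cure": est, "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


def doubling_time_summary(params: ModelParams, v=None) -> dict:
    """Median tumour volume-doubling time, in days, under two r-distributions.

    ``marginal``: the population Gamma(tau1, tau2) law of inverse growth
    rates.  ``detection_conditional``: the Gamma law of r given symptomatic
    detection at volume ``v`` (default: a 15 mm tumour), which favours slower
    tumours.  Both are reported because "the doubling time of detected
    tumours" depends on this conditioning.
    """
    g = params.growth
    ln2 = math.log(2.0)
    med_marginal = stats.gamma.ppf(0.5, g.tau1, scale=1.0 / g.tau2) * ln2
    if v is None:
        v = float(sphere_volume(15.0))
    rate = g.tau2 + g.eta * (v - V0)
    med_cond = stats.gamma.ppf(0.5, g.tau1 + 1.0, scale=1.0 / rate) * ln2
    return {
        "marginal_days": float(med_marginal * DAYS_PER_YEAR),
        "detection_conditional_days": float(med_cond * DAYS_PER_YEAR),
    }
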