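"""Maximum-likelihood inference for the joint natural-history model.

Optimisation runs on an unconstrained *transformed* scale — logs of the
positive parameters, the detection constant as ``-log(eta)``, and a
family-specific bijection for the copula association parameter — so that a
quasi-Newton optimiser can move freely.  Standard errors come from the
inverse of a central-finite-difference Hessian of the negative
log-likelihood at the optimum; 95% intervals are Wald intervals on the
transformed scale.  Derived quantities get delta-method standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .copulas import CopulaSpec
from .distant import DistantParams
from .geometry import GrowthParams, V0
from .likelihood import CohortArrays, LikelihoodOptions, cohort_logliks
from .nodal import NodalParams
from .params import ModelParams
from .screening import ScreeningParams

__all__ = [
    "PARAM_NAMES",
    "FitResult",
    "transform_params",
    "untransform_params",
    "free_mask",
    "default_init",
    "fit",
    "information_criteria",
    "lrt",
    "delta_method_se",
]

PARAM_NAMES = (
    "log_tau1",
    "log_tau2",
    "beta1",
    "beta2",
    "neg_log_eta",
    "log_omega1",
    "log_omega2",
    "log_gamma1",
    "log_gamma2",
    "theta_t",
)


def _theta_to_unconstrained(spec: CopulaSpec) -> float:
    th = spec.theta
    fam = spec.family
    if fam in ("frank", "product"):
        return th
    if fam == "amh":
        return math.atanh(min(max(th, -1 + 1e-12), 1 - 1e-12))
    if fam == "clayton":
        if th <= -1.0:
            raise ValueError("clayton theta must exceed -1 on the fitted branch")
        return math.log1p(th)
    if fam in ("gumbel", "joe"):
        if th < 1.0:
            raise ValueError(f"{fam} theta must be >= 1")
        return math.log(max(th - 1.0, 1e-12))
    raise AssertionError(fam)


def _theta_from_unconstrained(z: float, family: str) -> float:
    if family in ("frank", "product"):
        return z
    if family == "amh":
        return math.tanh(z)
    if family == "clayton":
        return math.expm1(z)
    if family in ("gumbel", "joe"):
        return 1.0 + math.exp(z)
    raise AssertionError(family)


def transform_params(params: ModelParams) -> np.ndarray:
    """Map ModelParams onto the unconstrained 10-vector (see PARAM_NAMES)."""
    g, n, d, s = params.growth, params.nodal, params.distant, params.screening
    return np.array(
        [
            math.log(g.tau1),
            math.log(g.tau2),
            s.beta1,
            s.beta2,
            -math.log(g.eta),
            math.log(d.omega1),
            math.log(d.omega2),
            math.log(n.gamma1),
            math.log(n.gamma2),
            _theta_to_unconstrained(params.copula),
        ]
    )


def untransform_params(vector, template: ModelParams) -> ModelParams:
    """Inverse of transform_params; copula family and k exponents come from template."""
    v = np.asarray(vector, dtype=float)
    fam = template.copula.family
    return ModelParams(
        growth=GrowthParams(tau1=math.exp(v[0]), tau2=math.exp(v[1]), eta=math.exp(-v[4])),
        nodal=NodalParams(gamma1=math.exp(v[7]), gamma2=math.exp(v[8]), k_n=template.nodal.k_n),
        distant=DistantParams(omega1=math.exp(v[5]), omega2=math.exp(v[6]), k_w=template.distant.k_w),
        screening=ScreeningParams(beta1=v[2], beta2=v[3]),
        copula=CopulaSpec(family=fam, theta=_theta_from_unconstrained(v[9], fam)),
    )


def free_mask(screened: bool, family: str) -> np.ndarray:
    """Which of the 10 coordinates are estimated: beta only with screening, theta unless product."""
    mask = np.ones(10, dtype=bool)
    if not screened:
        mask[2] = mask[3] = False
    if family == "product":
        mask[9] = False
    return mask


@dataclass
class FitResult:
    """ML estimates with transformed-scale covariance and fit diagnostics."""

    estimates: ModelParams
    transformed_estimates: np.ndarray
    free: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    aic: float
    bic: float
    converged: bool
    n_obs: int
    n_warnings: int = 0
    n_free: int = 0
    message: str = ""

    @property
    def free_names(self):
        return [nm for nm, f in zip(PARAM_NAMES, self.free) if f]

    def se(self) -> np.ndarray | None:
        """Standard errors of the free transformed parameters."""
        if self.vcov is None:
            return None
        return np.sqrt(np.maximum(np.diag(self.vcov), 0.0))

    def ci(self, level: float = 0.95):
        """Wald intervals (lower, upper) for the free transformed parameters."""
        se = self.se()
        if se is None:
            raise ValueError("no covariance available (singular Hessian?)")
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.transformed_estimates[self.free]
        return est - z * se, est + z * se

    def summary(self) -> dict:
        """Structured report of the fit (JSON-serialisable)."""
        out = {
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "n_warnings": self.n_warnings,
            "family": self.estimates.copula.family,
            "estimates": {},
        }
        se = self.se()
        free_est = self.transformed_estimates[self.free]
        for i, nm in enumerate(self.free_names):
            entry = {"estimate": float(free_est[i])}
            if se is not None:
                entry["se"] = float(se[i])
                entry["ci95"] = [float(free_est[i] - 1.959963984540054 * se[i]),
                                 float(free_est[i] + 1.959963984540054 * se[i])]
            out["estimates"][nm] = entry
        return out


def default_init(dataset, template: ModelParams) -> ModelParams:
    """Moment-style starting values from the observed cohort."""
    data = dataset if isinstance(dataset, CohortArrays) else CohortArrays(dataset)
    tau1, tau2 = 2.0, 2.5
    med_v = float(np.median(data.v))
    eta = tau2 * (2.0 ** (1.0 / tau1) - 1.0) / max(med_v - V0, 1.0)
    k_n = template.nodal.k_n
    a = np.log(data.v / V0)
    L = a ** (k_n + 1.0)
    mean_n = max(float(np.mean(data.n)), 0.05)
    var_n = max(float(np.var(data.n)), mean_n * 1.5)
    gamma1 = max(mean_n**2 / (var_n - mean_n), 0.05)
    gamma2 = gamma1 * float(np.mean(L)) / mean_n
    k_w = template.distant.k_w
    ev_frac = min(max(float(np.mean(data.is_event | data.is_left)), 0.02), 0.9)
    omega1 = 0.3
    bw = (a + 3.0) ** (k_w + 1.0)  # crude exposure a few years after diagnosis
    omega2 = float(np.mean(bw)) / max((1.0 - ev_frac) ** (-1.0 / omega1) - 1.0, 1e-3)
    med_d = float(np.median(data.d))
    beta2 = 0.5
    beta1 = -beta2 * med_d
    fam = template.copula.family
    theta0 = {"frank": -0.5, "clayton": -0.05, "amh": -0.1, "gumbel": 1.05, "joe": 1.05, "product": 0.0}[fam]
    return ModelParams(
        growth=GrowthParams(tau1=tau1, tau2=tau2, eta=eta),
        nodal=NodalParams(gamma1=gamma1, gamma2=gamma2, k_n=k_n),
        distant=DistantParams(omega1=omega1, omega2=omega2, k_w=k_w),
        screening=ScreeningParams(beta1=beta1, beta2=beta2),
        copula=CopulaSpec(family=fam, theta=theta0),
    )


def _hessian(f, x, rel_step: float = 5e-3):
    """Central-finite-difference Hessian with per-coordinate adaptive steps."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = f(x + 2 * ei)
        fmm = f(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4.0 * h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpq = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmq = f(x - ei + ej)
            fmn = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpq - fpm - fmq + fmn) / (4.0 * h[i] * h[j])
    return H


def fit(dataset, init: ModelParams | None = None, options: LikelihoodOptions | None = None,
        screened: bool | None = None, coarse: bool = True, compute_vcov: bool = True) -> FitResult:
    """Maximise the cohort log-likelihood over the transformed parameter vector.

    A short Nelder-Mead pass (``coarse=True``) precedes the quasi-Newton
    polish; non-convergence is flagged on the result, never raised, and a
    singular Hessian leaves ``vcov`` as ``None`` with a warning.
    """
    data = dataset if isinstance(dataset, CohortArrays) else CohortArrays(dataset)
    options = options or LikelihoodOptions()
    if screened is None:
        screened = data.any_screening
    template = init
    if template is None:
        raise ValueError("an initial ModelParams (template for family and k exponents) is required")
    mask = free_mask(screened, template.copula.family)
    x_full = transform_params(template)
    n_warn = 0

    def nll_free(z):
        nonlocal n_warn
        x = x_full.copy()
        x[mask] = z
        try:
            p = untransform_params(x, template)
            ll, nf = cohort_logliks(data, p, options, screened=screened)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12
        n_warn += nf
        val = float(-np.sum(ll))
        return val if np.isfinite(val) else 1e12

    z0 = x_full[mask]
    if coarse:
        res0 = optimize.minimize(nll_free, z0, method="Nelder-Mead",
                                 options={"maxiter": 200 * z0.size, "fatol": 1e-6, "xatol": 1e-6})
        z0 = res0.x
    res = optimize.minimize(nll_free, z0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
    if not res.success:
        # single restart from a jittered point, as plateaus near independence can stall
        res_retry = optimize.minimize(nll_free, res.x + 1e-3, method="L-BFGS-B",
                                      options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
        if res_retry.fun <= res.fun:
            res = res_retry
    z_hat = res.x
    x_hat = x_full.copy()
    x_hat[mask] = z_hat
    est = untransform_params(x_hat, template)
    loglik = -float(res.fun)
    k = int(mask.sum())
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(data.n_rec) - 2.0 * loglik
    vcov = None
    converged = bool(res.success)
    if compute_vcov:
        H = _hessian(nll_free, z_hat)
        try:
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            warnings.warn("Hessian at the optimum is numerically singular; no covariance")
            vcov = None
    return FitResult(
        estimates=est,
        transformed_estimates=x_hat,
        free=mask,
        vcov=vcov,
        loglik=loglik,
        aic=aic,
        bic=bic,
        converged=converged,
        n_obs=data.n_rec,
        n_warnings=n_warn,
        n_free=k,
        message=str(res.message),
    )


def information_criteria(result: FitResult):
    """(AIC, BIC) = (2k - 2 loglik, k log n - 2 loglik)."""
    return result.aic, result.bic


def lrt(fit_full: FitResult, fit_nested: FitResult, df: int | None = None):
    """Likelihood-ratio test of nested fits on the same data."""
    if fit_full.n_obs != fit_nested.n_obs:
        raise ValueError("fits are not on the same dataset")
    if df is None:
        df = fit_full.n_free - fit_nested.n_free
    if df < 0:
        raise ValueError("full model has fewer free parameters than the nested one")
    statistic = 2.0 * (fit_full.loglik - fit_nested.loglik)
    statistic = max(statistic, 0.0)
    p = 1.0 if df == 0 and statistic == 0.0 else float(stats.chi2.sf(statistic, max(df, 1)))
    if df == 0:
        p = 1.0 if statistic == 0.0 else 0.0
    return statistic, p


def delta_method_se(fn, result: FitResult, rel_step: float = 1e-5) -> float:
    """SE of a smooth scalar function of the free transformed parameters.

    ``fn`` receives the free transformed subvector; the gradient is central
    finite differences and the SE is sqrt(g' V g).
    """
    if result.vcov is None:
        raise ValueError("fit has no covariance matrix")
    z = result.transformed_estimates[result.free]
    k = z.size
    g = np.empty(k)
    h = rel_step * np.maximum(1.0, np.abs(z))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        g[i] = (fn(z + e) - fn(z - e)) / (2.0 * h[i])
    return float(math.sqrt(max(g @ result.vcov @ g, 0.0)))
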