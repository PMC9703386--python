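"""Synthetic cohorts, estimation-validation studies, and microsimulation.

``simulate_natural_history`` draws full latent histories: an inverse growth
rate per woman, a symptomatic-detection volume from the volume-proportional
hazard, competing screen detections at scheduled mammograms with logistic
size-dependent sensitivity, then a (node count, metastasis time) pair from
the copula joint law at the detected volume, discretised to years and
administratively censored.  The latent truths are kept alongside the records
so oracle tests can compare against the generating mechanism.

``simulate_validation_study`` repeats simulate-and-fit cycles and summarises
bias, empirical and model-based standard errors, and Wald coverage, with
Monte-Carlo errors.

``microsim_early_detection`` evaluates counterfactual earlier detection for a
large simulated tumour population: metastases seeded after the earlier
diagnosis date are removed (each seed surfaces a fixed ``t0(r)`` after being
shed, so the detected metastasis at ``W`` was seeded at ``W - t0``), and
five-year risks are reported both naively (clock starting at the earlier
diagnosis) and lead-time corrected (clock starting when the tumour would
have reached the original detection size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import copulas
from .cohort import PatientRecord, read_cohort, write_cohort
from .distant import prob_w_le0, w_quantile
from .geometry import V0, V_CELL, sphere_diameter, sphere_volume, t0 as t0_of
from .inference import fit as ml_fit, free_mask, transform_params
from .likelihood import LikelihoodOptions
from .nodal import node_quantile
from .params import ModelParams
from .screening import ScreeningHistory, sensitivity

__all__ = [
    "ScreeningProgram",
    "SyntheticCohort",
    "MicrosimScenario",
    "simulate_natural_history",
    "simulate_validation_study",
    "microsim_early_detection",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class ScreeningProgram:
    """Regular mammography schedule: fixed interval, uniform phase, capped history."""

    interval: float = 2.0
    max_screens: int = 10

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError("screening interval must be positive")


@dataclass
class SyntheticCohort:
    """Generated records plus the latent truths they were drawn from."""

    records: list
    truths: pd.DataFrame
    params: ModelParams
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        from .cohort import records_to_frame

        return records_to_frame(self.records)


@dataclass(frozen=True)
class MicrosimScenario:
    """Counterfactual early-detection settings for the microsimulation."""

    detection_diameter: float = 15.0
    earlier_by_time: tuple = (1.0, 2.0, 3.0)
    earlier_at_sizes: tuple = (10.0, 5.0, 1.0)
    horizon: float = 5.0
    n_tumours: int = 200_000
    seed: int | None = None

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if any(s >= self.detection_diameter for s in self.earlier_at_sizes):
            raise ValueError("counterfactual sizes must be below the detection size")
        if any(s <= 0.5 for s in self.earlier_at_sizes):
            raise ValueError("counterfactual sizes must exceed the 0.5 mm detectability limit")


def _follow_up(rng, n):
    # administrative censoring: per-woman follow-up, median ~5.5 years
    return rng.uniform(3.0, 8.0, size=n)


def simulate_natural_history(params: ModelParams, program: ScreeningProgram | None,
                             n: int, seed=None) -> SyntheticCohort:
    """Draw ``n`` incident cases under the full joint model.

    ``program=None`` disables screening entirely (all symptomatic).  The
    returned truths hold, per woman: r, t0, detected volume, mode, the latent
    copula uniforms, the latent (possibly unobserved) metastasis time, and
    the follow-up horizon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if program is not None and not isinstance(program, ScreeningProgram):
        raise ValueError("program must be a ScreeningProgram or None")
    rng = np.random.default_rng(seed)
    g = params.growth
    r = rng.gamma(shape=g.tau1, scale=1.0 / g.tau2, size=n)
    t0 = t0_of(r)
    # symptomatic detection: given r, V_sym = V0 + Exp(1) / (eta * r)
    v_sym = V0 + rng.exponential(size=n) / (g.eta * r)
    t_sym = t0 + r * np.log(v_sym / V0)

    mode = np.full(n, "symptomatic", dtype=object)
    v_det = v_sym.copy()
    t_det = t_sym.copy()
    screens: list[tuple] = [()] * n
    if program is not None:
        phase = rng.uniform(0.0, program.interval, size=n)
        for i in range(n):
            # screens at times phase + k*interval on the onset clock
            t_q = phase[i]
            negatives = []
            while t_q < t_det[i]:
                d_q = float(sphere_diameter(V_CELL * math.exp(t_q / r[i])))
                s_q = float(sensitivity(d_q, params.screening))
                if s_q > 0 and rng.uniform() < s_q:
                    mode[i] = "screen"
                    v_det[i] = float(sphere_volume(d_q))
                    t_det[i] = t_q
                    break
                negatives.append(t_q)
                t_q += program.interval
            offsets = tuple(round(t_det[i] - tq, 6) for tq in reversed(negatives) if t_det[i] - tq > 0)
            screens[i] = tuple(sorted(offsets))[: program.max_screens]

    # joint (N, W) at the detected volume via copula inversion of the margins
    u1, u2 = copulas.sample_copula(params.copula, n, seed=rng.integers(2**31 - 1))
    n_nodes = np.asarray(node_quantile(u1, v_det, params.nodal))
    w_latent = np.asarray(w_quantile(u2, v_det, r, params.distant), dtype=float)

    fup = _follow_up(rng, n)
    records = []
    w_years = np.zeros(n, dtype=int)
    status = np.full(n, "right", dtype=object)
    for i in range(n):
        if u2[i] <= float(prob_w_le0(v_det[i], params.distant)):
            status[i] = "left"
            w_years[i] = 0
        else:
            w_disc = math.ceil(w_latent[i]) if np.isfinite(w_latent[i]) else np.inf
            if w_disc <= math.floor(fup[i]):
                status[i] = "event"
                w_years[i] = max(int(w_disc), 1)
            else:
                status[i] = "right"
                w_years[i] = int(math.floor(fup[i]))
        records.append(
            PatientRecord(
                diameter_mm=float(sphere_diameter(v_det[i])),
                mode=str(mode[i]),
                screens=ScreeningHistory(screens[i]),
                n_nodes=int(n_nodes[i]),
                w_years=int(w_years[i]),
                status=str(status[i]),
            )
        )
    truths = pd.DataFrame(
        {
            "r": r,
            "t0": t0,
            "v_det": v_det,
            "t_det": t_det,
            "mode": mode,
            "u1": u1,
            "u2": u2,
            "n_nodes": n_nodes,
            "w_latent": w_latent,
            "follow_up": fup,
        }
    )
    return SyntheticCohort(records=records, truths=truths, params=params, seed=seed)


def simulate_validation_study(design: dict, seed=None) -> dict:
    """Repeated simulate-and-fit validation of the estimation procedure.

    ``design`` keys: ``n_patients``, ``n_reps``, ``truth`` (ModelParams),
    ``screening`` (ScreeningProgram or None), optional ``options``
    (LikelihoodOptions), ``init`` ("truth" or a ModelParams).  Failed fits are
    excluded and counted.  Returns the per-replicate estimates and a summary
    table with bias, Monte-Carlo error, empirical/model SEs and 95% coverage.
    """
    truth: ModelParams = design["truth"]
    n_patients = int(design["n_patients"])
    n_reps = int(design["n_reps"])
    program = design.get("screening")
    options = design.get("options") or LikelihoodOptions(n_quad_nodes=32)
    init = design.get("init", "truth")
    rng = np.random.default_rng(seed)
    screened = program is not None
    mask = free_mask(screened, truth.copula.family)
    z_truth = transform_params(truth)[mask]
    names = [nm for nm, f in zip(
        ("log_tau1", "log_tau2", "beta1", "beta2", "neg_log_eta", "log_omega1",
         "log_omega2", "log_gamma1", "log_gamma2", "theta_t"), mask) if f]
    ests, ses = [], []
    n_failed = 0
    for _ in range(n_reps):
        cohort = simulate_natural_history(truth, program, n_patients, seed=rng.integers(2**31 - 1))
        start = truth if init == "truth" else init
        res = ml_fit(cohort.records, init=start, options=options, screened=screened, coarse=False)
        if res.vcov is None or not np.all(np.isfinite(res.transformed_estimates)):
            n_failed += 1
            continue
        ests.append(res.transformed_estimates[mask])
        ses.append(res.se())
    ests = np.array(ests)
    ses = np.array(ses)
    n_ok = ests.shape[0]
    if n_ok == 0:
        raise RuntimeError("all replicate fits failed")
    bias = ests.mean(axis=0) - z_truth
    emp_se = ests.std(axis=0, ddof=1)
    mc_error = emp_se / math.sqrt(n_ok)
    lo = ests - 1.959963984540054 * ses
    hi = ests + 1.959963984540054 * ses
    coverage = np.mean((z_truth >= lo) & (z_truth <= hi), axis=0)
    summary = pd.DataFrame(
        {
            "parameter": names,
            "truth": z_truth,
            "mean_estimate": ests.mean(axis=0),
            "bias": bias,
            "mc_error": mc_error,
            "empirical_se": emp_se,
            "mean_model_se": ses.mean(axis=0),
            "coverage": coverage,
        }
    )
    return {"summary": summary, "estimates": ests, "ses": ses, "n_failed": n_failed,
            "n_reps_ok": n_ok, "truth_vector": z_truth, "names": names}


def _tertile_labels(r, params: ModelParams):
    from scipy import stats as sps

    g = params.growth
    q1, q2 = sps.gamma.ppf([1 / 3, 2 / 3], g.tau1, scale=1.0 / g.tau2)
    lab = np.where(r <= q1, "fast", np.where(r <= q2, "medium", "slow"))
    return lab  # small r = fast growth


def microsim_early_detection(scenario: MicrosimScenario, params: ModelParams) -> pd.DataFrame:
    """Counterfactual early-detection risk table.

    For each scenario (baseline detection at ``detection_diameter``; earlier
    by Delta years; earlier at a smaller diameter) and each stratum (node
    count 0/1/2 at the original detection size x inverse-growth-rate
    tertile), reports the naive and lead-time-corrected risks of a distant
    metastasis diagnosis within ``horizon`` years, plus the average size at
    (or time to reach) the counterfactual detection point.
    """
    rng = np.random.default_rng(scenario.seed)
    g = params.growth
    n = scenario.n_tumours
    r = rng.gamma(shape=g.tau1, scale=1.0 / g.tau2, size=n)
    v = float(sphere_volume(scenario.detection_diameter))
    t0 = t0_of(r)
    u1, u2 = copulas.sample_copula(params.copula, n, seed=rng.integers(2**31 - 1))
    n_nodes = node_quantile(u1, v, params.nodal)
    w = np.asarray(w_quantile(u2, v, r, params.distant))
    # condition on no detectable metastasis at the original diagnosis
    alive = u2 > float(prob_w_le0(v, params.distant))
    tert = _tertile_labels(r, params)

    scenarios = [("baseline", "time", 0.0)]
    scenarios += [("time", "time", float(d)) for d in scenario.earlier_by_time]
    scenarios += [("size", "size", float(s)) for s in scenario.earlier_at_sizes]

    rows = []
    for kind, axis, val in scenarios:
        if axis == "time":
            delta = np.full(n, val)
            annot_key, annot = "mean_diameter_mm", None
        else:
            v_prime = float(sphere_volume(val))
            delta = r * math.log(v / v_prime)
            annot_key, annot = "mean_years_earlier", None
        # a metastasis detected at W was seeded at W - t0; seeds after -delta are removed
        occurs = w <= (t0 - delta)
        naive = occurs & (w + delta <= scenario.horizon) & (w + delta > 0)
        corrected = occurs & (w <= scenario.horizon)
        d_at = sphere_diameter(np.maximum(v * np.exp(-delta / r), V_CELL))
        for nodes in (0, 1, 2):
            for tlab in ("fast", "medium", "slow"):
                m = alive & (n_nodes == nodes) & (tert == tlab)
                n_m = int(m.sum())
                if n_m == 0:
                    continue
                rows.append(
                    {
                        "scenario": kind,
                        "value": val,
                        "node_group": nodes,
                        "tertile": tlab,
                        "n": n_m,
                        "naive_risk": float(naive[m].mean()),
                        "corrected_risk": float(corrected[m].mean()),
                        "mean_diameter_mm": float(d_at[m].mean()),
                        "mean_years_earlier": float(delta[m].mean()),
                    }
                )
    return pd.DataFrame(rows)
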