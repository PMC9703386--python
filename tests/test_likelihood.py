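import math

import numpy as np
import pytest
from scipy import integrate, stats

from natmet import copulas
from natmet.cohort import PatientRecord
from natmet.geometry import V0, V_CELL, sphere_volume, vdet_pdf
from natmet.likelihood import (
    CohortArrays,
    LikelihoodOptions,
    _fw_discrete,
    cohort_logliks,
    loglik_screened,
    loglik_unscreened,
    total_negloglik,
)
from natmet.nodal import node_cdf, node_pmf
from natmet.screening import ScreeningHistory


def _w_cell_integral(params, v, n, w, status):
    """Adaptive-quadrature oracle for the r-integrated (N, W) cell."""
    g = params.growth
    a, b = math.log(v / V0), math.log(v / V_CELL)
    rate = g.tau2 + g.eta * (v - V0)
    fnh = float(node_cdf(n, v, params.nodal))
    fnl = float(node_cdf(n - 1, v, params.nodal)) if n > 0 else 0.0

    def cell(r):
        fw = float(_fw_discrete(w / r + a, b, params))
        if status == "event":
            fwl = float(_fw_discrete(max(w - 1, 0) / r + a, b, params))
            return float(copulas.rect_event(fnl, fnh, fwl, fw, params.copula))
        return float(copulas.rect_right(fnl, fnh, fw, params.copula))

    K = math.log(V0 / V_CELL)
    pts = sorted({max(w - 1, 0) / K, w / K, 4 * w / K})
    total = 0.0
    lo = 0.0
    for hi in pts + [80.0]:
        if hi > lo:
            val, _ = integrate.quad(
                lambda r: cell(r) * stats.gamma.pdf(r, g.tau1 + 1.0, scale=1.0 / rate),
                lo,
                hi,
                limit=300,
            )
            total += val
        lo = hi
    return total


class TestUnscreenedContributions:
    @pytest.mark.parametrize(
        "n,w,status",
        [(0, 1, "event"), (2, 3, "event"), (1, 5, "right"), (0, 8, "right"), (1, 0, "left")],
    )
    def test_matches_adaptive_quadrature_oracle(self, ref_params, n, w, status):
        rec = PatientRecord(diameter_mm=18.0, mode="symptomatic", n_nodes=n, w_years=w, status=status)
        ll = loglik_unscreened(rec, ref_params)
        v = float(sphere_volume(18.0))
        if status == "left":
            from natmet.distant import prob_w_le0

            fw0 = float(prob_w_le0(v, ref_params.distant))
            fnh = float(node_cdf(n, v, ref_params.nodal))
            fnl = float(node_cdf(n - 1, v, ref_params.nodal)) if n > 0 else 0.0
            cell = float(copulas.copula_cdf(fnh, fw0, ref_params.copula)) - float(
                copulas.copula_cdf(fnl, fw0, ref_params.copula)
            )
        else:
            cell = _w_cell_integral(ref_params, v, n, w, status)
        oracle = math.log(float(vdet_pdf(v, ref_params.growth))) + math.log(cell)
        assert ll == pytest.approx(oracle, abs=1e-7)

    def test_product_copula_factorises(self, product_params):
        """Under independence the contribution splits into size, node and
        metastasis-time factors."""
        p = product_params
        rec = PatientRecord(diameter_mm=22.0, mode="symptomatic", n_nodes=2, w_years=4, status="event")
        ll = loglik_unscreened(rec, p)
        v = float(sphere_volume(22.0))
        g = p.growth
        a, b = math.log(v / V0), math.log(v / V_CELL)
        rate = g.tau2 + g.eta * (v - V0)
        w_term, _ = integrate.quad(
            lambda r: (float(_fw_discrete(4.0 / r + a, b, p)) - float(_fw_discrete(3.0 / r + a, b, p)))
            * stats.gamma.pdf(r, g.tau1 + 1.0, scale=1.0 / rate),
            0,
            60.0,
            limit=400,
        )
        expected = (
            math.log(float(vdet_pdf(v, g)))
            + math.log(float(node_pmf(2, v, p.nodal)))
            + math.log(w_term)
        )
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_quadrature_converged_at_defaults(self, ref_params):
        recs = [
            PatientRecord(diameter_mm=d, mode="symptomatic", n_nodes=n, w_years=w, status=s)
            for d, n, w, s in [(9.0, 0, 1, "event"), (15.0, 1, 2, "event"), (30.0, 4, 6, "right"),
                               (15.0, 0, 12, "right"), (40.0, 2, 0, "left")]
        ]
        ll64, _ = cohort_logliks(recs, ref_params, LikelihoodOptions(n_quad_nodes=64))
        ll128, _ = cohort_logliks(recs, ref_params, LikelihoodOptions(n_quad_nodes=128))
        assert np.max(np.abs(ll64 - ll128)) < 1e-6

    def test_statuses_partition_node_marginal(self, ref_params):
        """left + events + right-at-horizon recover the node pmf after
        dividing out the size density."""
        v = float(sphere_volume(17.0))
        d = 17.0
        for n in (0, 1, 3):
            pieces = [
                math.exp(loglik_unscreened(
                    PatientRecord(diameter_mm=d, mode="symptomatic", n_nodes=n, w_years=0, status="left"),
                    ref_params))
            ]
            grid_max = 25
            for w in range(1, grid_max + 1):
                pieces.append(math.exp(loglik_unscreened(
                    PatientRecord(diameter_mm=d, mode="symptomatic", n_nodes=n, w_years=w, status="event"),
                    ref_params)))
            pieces.append(math.exp(loglik_unscreened(
                PatientRecord(diameter_mm=d, mode="symptomatic", n_nodes=n, w_years=grid_max, status="right"),
                ref_params)))
            total = sum(pieces) / float(vdet_pdf(v, ref_params.growth))
            assert total == pytest.approx(float(node_pmf(n, v, ref_params.nodal)), abs=1e-8)


class TestScreenedContributions:
    def test_reduces_to_unscreened_without_screens(self, ref_params):
        rec = PatientRecord(diameter_mm=14.0, mode="symptomatic", n_nodes=1, w_years=2, status="event")
        assert loglik_screened(rec, ref_params) == pytest.approx(
            loglik_unscreened(rec, ref_params), abs=1e-12
        )

    def test_screen_detection_adds_sensitivity_factor(self, ref_params):
        from natmet.screening import sensitivity

        sym = PatientRecord(diameter_mm=14.0, mode="symptomatic", n_nodes=1, w_years=2, status="event")
        scr = PatientRecord(diameter_mm=14.0, mode="screen", n_nodes=1, w_years=2, status="event")
        delta = loglik_screened(scr, ref_params) - loglik_screened(sym, ref_params)
        assert delta == pytest.approx(
            math.log(float(sensitivity(14.0, ref_params.screening))), abs=1e-12
        )

    def test_negative_screens_lower_fast_growth_weight(self, ref_params):
        """A recent negative screen shifts mass towards fast tumours and
        changes the contribution by the r-integrated screen product."""
        base = PatientRecord(diameter_mm=20.0, mode="symptomatic", n_nodes=0, w_years=3, status="event")
        hist = PatientRecord(
            diameter_mm=20.0, mode="symptomatic", n_nodes=0, w_years=3, status="event",
            screens=ScreeningHistory((1.0,)),
        )
        assert loglik_screened(hist, ref_params) < loglik_screened(base, ref_params)

    def test_left_censored_screen_detected_integrates_history(self, ref_params):
        """The r-free (N, W<=0) cell multiplies the r-integrated screen
        product and the sensitivity factor."""
        from natmet.distant import prob_w_le0
        from natmet.geometry import r_given_vdet_quadrature
        from natmet.screening import negative_screens_likelihood, sensitivity

        rec = PatientRecord(
            diameter_mm=25.0, mode="screen", n_nodes=1, w_years=0, status="left",
            screens=ScreeningHistory((2.0, 4.0)),
        )
        ll = loglik_screened(rec, ref_params)
        v = float(sphere_volume(25.0))
        nodes, wts = r_given_vdet_quadrature(v, ref_params.growth, 128)
        sp = float(np.sum(wts * negative_screens_likelihood(rec.screens, v, nodes, ref_params.screening)))
        fw0 = float(prob_w_le0(v, ref_params.distant))
        fnh = float(node_cdf(1, v, ref_params.nodal))
        fnl = float(node_cdf(0, v, ref_params.nodal))
        cell = float(copulas.copula_cdf(fnh, fw0, ref_params.copula)) - float(
            copulas.copula_cdf(fnl, fw0, ref_params.copula)
        )
        expected = (
            math.log(float(vdet_pdf(v, ref_params.growth)))
            + math.log(cell)
            + math.log(sp)
            + math.log(float(sensitivity(25.0, ref_params.screening)))
        )
        # the 0.5 mm screening threshold puts a small kink in the r-integrand,
        # so fixed-rule and reference quadrature agree only to ~1e-3 here
        assert ll == pytest.approx(expected, abs=5e-3)


class TestMonteCarloOracle:
    def test_joint_cells_match_mechanism_frequencies(self, ref_params):
        """Cell probabilities at a fixed detected volume agree with draws from
        r | Vdet, the copula, and the discretised margins."""
        rng = np.random.default_rng(321)
        p = ref_params
        v = float(sphere_volume(15.0))
        g = p.growth
        rate = g.tau2 + g.eta * (v - V0)
        n_draws = 1_000_000
        r = rng.gamma(g.tau1 + 1.0, 1.0 / rate, size=n_draws)
        u1, u2 = copulas.sample_copula(p.copula, n_draws, seed=17)
        from natmet.distant import w_quantile
        from natmet.nodal import node_quantile

        n_samp = np.asarray(node_quantile(u1, v, p.nodal))
        w_lat = np.asarray(w_quantile(u2, v, r, p.distant))
        w_samp = np.where(np.isfinite(w_lat), np.ceil(np.nan_to_num(w_lat, posinf=-1.0)), -1).astype(int)
        left = u2 <= float(_fw_discrete(math.log(v / V0), math.log(v / V_CELL), p))
        for n, w, status in [(0, 1, "event"), (1, 2, "event"), (0, 5, "right"), (2, 0, "left")]:
            if status == "left":
                freq = float(np.mean(left & (n_samp == n)))
            elif status == "event":
                freq = float(np.mean(~left & (n_samp == n) & (w_samp == w)))
            else:
                freq = float(np.mean((n_samp == n) & (~left) & ((w_samp > w) | (w_samp < 0))))
            rec = PatientRecord(diameter_mm=15.0, mode="symptomatic", n_nodes=n,
                                w_years=w, status=status)
            prob = math.exp(loglik_unscreened(rec, p)) / float(vdet_pdf(v, p.growth))
            se = math.sqrt(prob * (1 - prob) / n_draws)
            assert abs(freq - prob) < 3 * se + 1e-9


class TestTotals:
    def test_single_record_and_additivity(self, ref_params):
        recs = [
            PatientRecord(diameter_mm=12.0, mode="symptomatic", n_nodes=0, w_years=2, status="event"),
            PatientRecord(diameter_mm=25.0, mode="symptomatic", n_nodes=3, w_years=5, status="right"),
        ]
        nll = total_negloglik(recs, ref_params)
        parts = [total_negloglik([r], ref_params) for r in recs]
        assert nll == pytest.approx(sum(parts), rel=1e-12)
        assert parts[0] == pytest.approx(-loglik_unscreened(recs[0], ref_params), rel=1e-12)

    def test_permutation_invariance(self, ref_params, unscreened_cohort):
        recs = unscreened_cohort.records[:200]
        shuffled = list(recs)
        np.random.default_rng(3).shuffle(shuffled)
        assert total_negloglik(recs, ref_params) == pytest.approx(
            total_negloglik(shuffled, ref_params), rel=1e-12
        )

    def test_empty_dataset_errors(self, ref_params):
        with pytest.raises(ValueError):
            total_negloglik([], ref_params)

    def test_likelihood_dominance_at_truth(self, ref_params):
        """On a large simulated cohort the generating parameters beat +/-20%
        perturbations of each component."""
        from natmet.inference import transform_params, untransform_params
        from natmet.simulate import simulate_natural_history

        cohort = simulate_natural_history(ref_params, None, 5000, seed=55)
        data = CohortArrays(cohort.records)
        nll_truth = total_negloglik(data, ref_params, screened=False)
        x = transform_params(ref_params)
        rng = np.random.default_rng(8)
        for _ in range(5):
            pert = x * (1.0 + rng.uniform(-0.2, 0.2, size=x.size))
            pert[2:4] = x[2:4]  # screening betas are not in the unscreened likelihood
            nll_pert = total_negloglik(data, untransform_params(pert, ref_params), screened=False)
            assert nll_pert > nll_truth
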