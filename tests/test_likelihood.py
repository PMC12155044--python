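"""Observation-model density: limits, oracles, normalization, additivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import lognorm

from serorate import (CrossSectionalLikelihood, DensityZeroError,
                      LikelihoodOptions, NoiseParams, ObservationModel,
                      PopData, SRParamEnsemble, closed_form_density_no_noise,
                      neg_log_lik, obs_cdf, obs_density)
from serorate.data_model import DAYS_PER_YEAR
from serorate.likelihood import _cdf_kernel, _never_cdf, _never_pdf, _pdf_kernel


def single_draw_ensemble(**kw):
    row = dict(antigen_iso="X", y0=1.0, y1=100.0, t1=10.0, alpha=0.01, r=2.0)
    row.update(kw)
    return SRParamEnsemble(pd.DataFrame([row]))


def model_for(ens, nu=1.0, eps=0.2, y_low=0.0, y_high=1e12, ai="X", **opt):
    nz = NoiseParams(ai, nu=nu, eps=eps, y_low=y_low, y_high=y_high)
    options = LikelihoodOptions(**opt) if opt else None
    return ObservationModel.from_inputs(ens, {ai: nz}, ai, options=options)


class TestNoiseKernels:
    """Closed-form Uniform(0,ν)×LogNormal convolution vs numeric quadrature."""

    @pytest.mark.parametrize("m,nu,eps,y", [
        (0.0, 2.0, 0.3, 1.0),
        (2.0, 1.5, 0.2, 2.7),
        (5.0, 0.5, 0.1, 5.6),
        (0.3, 3.0, 0.45, 0.2),
    ])
    def test_pdf_matches_numeric_convolution(self, m, nu, eps, y):
        sigma = np.sqrt(np.log1p(eps ** 2))
        scale = np.exp(-0.5 * sigma ** 2)
        ref, _ = integrate.quad(
            lambda b: lognorm.pdf(y, sigma, scale=(m + b) * scale) / nu,
            0, nu, limit=200)
        got = float(_pdf_kernel(y, np.array(m), nu, sigma))
        assert got == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("m,nu,eps,c", [
        (0.0, 2.0, 0.3, 1.0),
        (2.0, 1.5, 0.2, 2.7),
        (0.3, 3.0, 0.45, 0.2),
    ])
    def test_cdf_matches_numeric_convolution(self, m, nu, eps, c):
        sigma = np.sqrt(np.log1p(eps ** 2))
        scale = np.exp(-0.5 * sigma ** 2)
        ref, _ = integrate.quad(
            lambda b: lognorm.cdf(c, sigma, scale=(m + b) * scale) / nu,
            0, nu, limit=200)
        got = float(_cdf_kernel(c, np.array(m), nu, sigma))
        assert got == pytest.approx(ref, rel=1e-9, abs=1e-14)

    def test_cdf_is_integral_of_pdf(self):
        nu, sigma, m = 1.5, 0.25, 1.2
        for c in (0.5, 2.0, 4.0):
            ref, _ = integrate.quad(
                lambda y: float(_pdf_kernel(y, np.array(m), nu, sigma)),
                0, c, limit=300)
            assert float(_cdf_kernel(c, np.array(m), nu, sigma)) == \
                pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_sigma_zero_reduces_to_uniform(self):
        assert float(_pdf_kernel(1.0, np.array(0.5), 2.0, 0.0)) == 0.5
        assert float(_pdf_kernel(3.0, np.array(0.5), 2.0, 0.0)) == 0.0
        assert float(_never_cdf(np.array(1.0), 2.0, 0.0)) == 0.5
        assert float(_never_pdf(np.array(1.0), 2.0, 0.0)) == 0.5


class TestObsDensity:
    def test_lambda_to_zero_limit_is_never_infected_noise(self):
        """As λ→0 the density is just the never-infected noise floor 1/ν."""
        ens = single_draw_ensemble()
        m = model_for(ens, nu=2.0, eps=0.0)
        assert obs_density(1.0, 10.0, 1e-12, m) == pytest.approx(0.5, rel=1e-9)

    def test_matches_closed_form_in_no_noise_decay_limit(self, toy_draw):
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.0, mode="noise-free",
                      include_rise=False)
        lam, age = 0.2, 10.0
        floor = 100.0 / (1 + 0.01 * 100 * (age * DAYS_PER_YEAR - 10))
        ys = np.geomspace(floor * 1.05, 99.9, 8)
        q = obs_density(ys, age, lam, m)
        cf = closed_form_density_no_noise(ys, age, lam, toy_draw)
        np.testing.assert_allclose(q, cf, rtol=1e-4)

    def test_monte_carlo_oracle(self):
        """Brute-force simulation of the generative model reproduces the
        probability the density assigns to a window around y=3."""
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.2)
        lam, age = 0.2, 10.0
        lam_day = lam / DAYS_PER_YEAR
        a_days = age * DAYS_PER_YEAR
        rng = np.random.default_rng(12345)
        n = 2_000_000
        never = rng.uniform(size=n) < np.exp(-lam_day * a_days)
        u = rng.uniform(size=n)
        tau = -np.log1p(-u * (1 - np.exp(-lam_day * a_days))) / lam_day
        mu = np.log(100.0) / 10.0
        y_model = np.where(tau <= 10.0, np.exp(mu * np.minimum(tau, 10.0)),
                           100.0 / (1 + 0.01 * 100 * np.maximum(tau - 10, 0)))
        y_model[never] = 0.0
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        e = np.exp(sigma * rng.standard_normal(n) - sigma ** 2 / 2)
        y_obs = (y_model + rng.uniform(0, 1.0, size=n)) * e
        lo, hi = 2.8, 3.2
        p_emp = np.mean((y_obs >= lo) & (y_obs <= hi))
        se = np.sqrt(p_emp * (1 - p_emp) / n)
        p_model, _ = integrate.quad(lambda y: obs_density(y, age, lam, m),
                                    lo, hi, limit=200)
        assert abs(p_model - p_emp) < 3 * se

    def test_normalization_with_censoring(self):
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.2, y_low=0.1, y_high=5000.0)
        lam, age = 0.2, 10.0
        dens, _ = integrate.quad(lambda y: obs_density(y, age, lam, m),
                                 0.1, 5000.0, limit=400)
        mass_low = obs_density(0.05, age, lam, m)
        mass_high = obs_density(6000.0, age, lam, m)
        assert dens + mass_low + mass_high == pytest.approx(1.0, abs=1e-3)

    def test_censored_masses_monotone_in_lambda(self):
        """More infections → higher titres: P(Y≤y_low) falls and P(Y≥y_high)
        rises with λ."""
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.2, y_low=0.5, y_high=50.0)
        lams = np.geomspace(0.01, 2.0, 8)
        low = [obs_density(0.2, 8.0, l, m) for l in lams]
        high = [obs_density(60.0, 8.0, l, m) for l in lams]
        assert np.all(np.diff(low) < 0)
        assert np.all(np.diff(high) > 0)

    def test_cdf_matches_integrated_density(self):
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.2)
        lam, age = 0.3, 9.0
        for c in (0.7, 3.0, 40.0):
            ref, _ = integrate.quad(lambda y: obs_density(y, age, lam, m),
                                    1e-12, c, limit=400)
            assert obs_cdf(c, age, lam, m) == pytest.approx(ref, rel=2e-6)

    def test_quadrature_check_passes_on_default_grid(self):
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.2, check_quadrature=True,
                      rel_tol=1e-4)
        ys = np.array([0.3, 1.0, 3.0, 30.0, 90.0])
        p = obs_density(ys, 10.0, 0.2, m)
        assert np.all(p > 0)

    def test_invalid_lambda_rejected(self, toy_model):
        with pytest.raises(Exception, match="lambda"):
            obs_density(1.0, 10.0, -0.1, toy_model)


class TestClosedForm:
    def test_total_probability_on_decay_range(self, toy_draw):
        """The decay-only density integrates to the probability that the
        latent infection time falls on the decay branch,
        exp(-λ t1) - exp(-λ a)."""
        lam, age = 0.4, 12.0
        lam_day = lam / DAYS_PER_YEAR
        a_days = age * DAYS_PER_YEAR
        floor = 100.0 / (1 + 0.01 * 100 * (a_days - 10))
        val, _ = integrate.quad(
            lambda y: closed_form_density_no_noise(y, age, lam, toy_draw),
            floor, 100.0, limit=500)
        expect = np.exp(-lam_day * toy_draw.t1) - np.exp(-lam_day * a_days)
        assert val == pytest.approx(expect, rel=1e-6)

    def test_exponential_shape_at_peak(self):
        """For r=1 the density at the peak is λ e^{-λ t1} / (alpha y1)."""
        from serorate import SeroresponseDraw
        draw = SeroresponseDraw("X", y0=1.0, y1=50.0, t1=5.0, alpha=0.02,
                                r=1.0)
        lam, age = 0.2, 10.0
        lam_day = lam / DAYS_PER_YEAR
        got = closed_form_density_no_noise(50.0, age, lam, draw)
        assert got == pytest.approx(
            lam_day * np.exp(-lam_day * 5.0) / (0.02 * 50.0), rel=1e-12)

    def test_outside_range_is_zero_not_error(self, toy_draw):
        assert closed_form_density_no_noise(101.0, 10.0, 0.2, toy_draw) == 0.0
        assert closed_form_density_no_noise(1e-6, 10.0, 0.2, toy_draw) == 0.0


class TestNegLogLik:
    def _pop(self, rows):
        return PopData(pd.DataFrame(rows))

    def test_definitional_sum_over_records(self):
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.2)
        pop = self._pop([
            {"id": "a", "age": 5.0, "antigen_iso": "X", "value": 1.1},
            {"id": "b", "age": 8.0, "antigen_iso": "X", "value": 3.0},
            {"id": "c", "age": 12.0, "antigen_iso": "X", "value": 40.0}])
        lam = 0.3
        expected = -sum(np.log(obs_density(r.value, r.age, lam, m))
                        for r in pop.df.itertuples())
        assert neg_log_lik(lam, pop, {"X": m}) == pytest.approx(
            expected, rel=1e-12)

    def test_additive_across_biomarkers_exactly(self):
        ens = SRParamEnsemble(pd.DataFrame([
            dict(antigen_iso="A", y0=1.0, y1=100.0, t1=10.0, alpha=0.01, r=2.0),
            dict(antigen_iso="B", y0=0.8, y1=60.0, t1=8.0, alpha=0.02, r=1.5)]))
        mA = model_for(ens, nu=1.0, eps=0.2, ai="A")
        mB = model_for(ens, nu=1.5, eps=0.1, ai="B")
        rows = []
        rng = np.random.default_rng(5)
        for i in range(40):
            rows.append({"id": f"s{i}", "age": float(rng.uniform(2, 15)),
                         "antigen_iso": "A",
                         "value": float(rng.uniform(0.2, 80))})
            rows.append({"id": f"s{i}", "age": rows[-1]["age"],
                         "antigen_iso": "B",
                         "value": float(rng.uniform(0.2, 50))})
        pop = self._pop(rows)
        lam = 0.25
        combined = neg_log_lik(lam, pop, {"A": mA, "B": mB})
        only_a = neg_log_lik(lam, pop.subset(["A"]), {"A": mA})
        only_b = neg_log_lik(lam, pop.subset(["B"]), {"B": mB})
        assert combined == only_a + only_b  # bit-for-bit

    def test_impossible_value_raises_density_zero(self):
        ens = single_draw_ensemble()
        m = model_for(ens, nu=1.0, eps=0.0)  # max attainable y is y1 + nu
        pop = self._pop([{"id": "a", "age": 5.0, "antigen_iso": "X",
                          "value": 500.0}])
        with pytest.raises(DensityZeroError, match="a"):
            neg_log_lik(0.2, pop, {"X": m})

    def test_analytic_derivatives_match_finite_differences(self, igg_survey,
                                                           igg_ensemble,
                                                           igg_noise):
        _, pop, _ = igg_survey
        m = ObservationModel.from_inputs(igg_ensemble, igg_noise, "HlyE_IgG")
        lik = CrossSectionalLikelihood(pop, {"HlyE_IgG": m})
        x = np.log(0.3)
        val, grad, hess = lik.nll_derivs(x, order=2)
        h = 1e-5
        fp, fm = lik.nll(np.exp(x + h)), lik.nll(np.exp(x - h))
        assert val == pytest.approx(lik.nll(np.exp(x)), rel=1e-12)
        assert grad == pytest.approx((fp - fm) / (2 * h), rel=1e-5)
        assert hess == pytest.approx((fp - 2 * val + fm) / h ** 2, rel=1e-3)

    def test_grid_minimum_near_generating_rate(self):
        """Across seeded 200-subject replicates of the default two-biomarker
        survey, the NLL over a 50-point log-λ grid spanning the search bounds
        is minimized within one grid step of the generating λ in at least 90%
        of replicates."""
        from serorate import (SimulationConfig, default_ensemble,
                              default_noise, simulate_pop_data)
        lam_true = 0.2
        # log-spaced grid spanning three decades either side of the
        # generating rate, with the generating rate itself on the grid
        grid = lam_true * np.exp(np.linspace(-np.log(1000), np.log(1000), 49))
        step = np.log(grid[1]) - np.log(grid[0])
        ens = default_ensemble(K=20, seed=0)
        noise = default_noise()
        models = {ai: ObservationModel.from_inputs(ens, noise, ai)
                  for ai in ("HlyE_IgA", "HlyE_IgG")}
        hits = 0
        n_rep = 50
        for seed in range(1, n_rep + 1):
            cfg = SimulationConfig(lambda_true=lam_true, n_subjects=200,
                                   ensemble=ens, noise=noise, seed=seed)
            pop = simulate_pop_data(cfg)
            lik = CrossSectionalLikelihood(pop, models)
            nlls = [lik.nll(l) for l in grid]
            best = grid[int(np.argmin(nlls))]
            if abs(np.log(best) - np.log(lam_true)) <= step + 1e-12:
                hits += 1
        assert hits / n_rep >= 0.90
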