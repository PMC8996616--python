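"""Movement kernels and weighting functions against independent oracles."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

import memstep as ms
from memstep.errors import UndefinedMemoryError
from memstep.kernels import (STATIONARY_MEAN_KM, STATIONARY_SCALE_KM,
                             crw_density, draw_candidates, f_ns_hat,
                             sample_stationary_length, stationary_density,
                             wrapped_cauchy_pdf, wrapped_cauchy_ppf)
from memstep.params import BETA0_FIXED_MEMORY


class TestWrappedCauchy:
    @pytest.mark.parametrize("kappa", [0.2, 0.5, 0.9])
    def test_matches_scipy(self, kappa):
        theta = np.linspace(-np.pi + 1e-6, np.pi, 25)
        ours = wrapped_cauchy_pdf(theta, kappa)
        ref = stats.wrapcauchy.pdf(np.mod(theta, 2 * np.pi), kappa)
        assert np.allclose(ours, ref, rtol=1e-10)

    def test_kappa_zero_uniform(self):
        theta = np.linspace(-np.pi, np.pi, 9)
        assert np.allclose(wrapped_cauchy_pdf(theta, 0.0), 1 / (2 * np.pi))

    @pytest.mark.parametrize("kappa", [0.0, 0.4, 0.8])
    def test_ppf_inverts_cdf(self, kappa):
        u = np.linspace(0.01, 0.99, 21)
        theta = wrapped_cauchy_ppf(u, kappa)
        # numeric CDF from the pdf recovers u
        cdf = [0.5 + integrate.quad(
            lambda x: wrapped_cauchy_pdf(x, kappa), 0, t)[0] for t in theta]
        assert np.allclose(cdf, u, atol=1e-8)

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            wrapped_cauchy_pdf(0.1, 1.0)


class TestCRWDensity:
    def test_integrates_to_one_polar(self):
        rho, kappa, dt = 0.4, 0.6, 4.0
        mean_len = rho * dt

        def integrand(theta, r):
            return crw_density(r, theta, rho, kappa, dt) * r

        val, _ = integrate.dblquad(integrand, 1e-6, 10 * mean_len,
                                   -np.pi, np.pi, epsabs=1e-6)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_kappa_zero_angle_factor(self):
        # ratio of densities at two angles is 1 when kappa = 0
        a = crw_density(1.0, 0.3, 0.4, 0.0, 4.0)
        b = crw_density(1.0, 2.9, 0.4, 0.0, 4.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_sampled_mean_length(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(size=(100_000, 2))
        cs = draw_candidates(u, (0, 0), 0.0, rho_ns=0.4, kappa=0.5,
                             dt_hours=4.0)
        lengths = np.hypot(*cs.endpoints.T)
        se = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 1.6) < 3 * se

    def test_undefined_heading_uniform_direction(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(size=(20_000, 2))
        cs = draw_candidates(u, (0, 0), np.nan, 0.4, 0.9, 4.0)
        angles = np.arctan2(cs.endpoints[:, 1], cs.endpoints[:, 0])
        # Rayleigh test statistic should not flag concentration
        R = np.hypot(np.cos(angles).mean(), np.sin(angles).mean())
        assert 2 * len(angles) * R ** 2 < stats.chi2.ppf(0.99, 2)


class TestStationary:
    def test_negative_length_zero(self):
        assert stationary_density(-0.01) == 0.0

    def test_mean_is_30_m(self):
        # quadrature of l * f(l), and the half-normal closed form
        val, _ = integrate.quad(lambda l: l * stationary_density(l), 0, 1.0)
        assert val == pytest.approx(STATIONARY_MEAN_KM, abs=1e-9)
        assert STATIONARY_SCALE_KM * np.sqrt(2 / np.pi) == pytest.approx(0.03)

    def test_monte_carlo_mean(self):
        rng = np.random.default_rng(2)
        draws = sample_stationary_length(rng, size=1_000_000)
        se = draws.std() / 1000.0
        assert abs(draws.mean() - 0.03) < 3 * se

    def test_lighter_tail_than_exponential(self):
        # P(L > 3 mean): half-normal vs exponential with the same mean
        m = STATIONARY_MEAN_KM
        p_half = 2 * stats.norm.sf(3 * m, scale=STATIONARY_SCALE_KM)
        p_exp = np.exp(-3.0)
        assert p_half < p_exp


class TestWeightingFunctions:
    def test_w_null_is_one_everywhere(self):
        assert ms.w_null((3.0, 4.0)) == 1.0
        assert ms.w_null((-1e6, 1e6)) == 1.0

    def test_w_resource_closed_forms(self):
        assert ms.w_resource(np.zeros(6), np.zeros(6)) == 1.0
        r = np.array([1.0, 0, 0, 0, 0, 0])
        b = np.array([0.5, 0, 0, 0, 0, 0])
        assert ms.w_resource(r, b) == pytest.approx(np.exp(0.5))

    def test_w_resource_monotone(self):
        b = np.array([0.7, 0, 0, 0, 0, 0])
        lo = ms.w_resource(np.array([0.2, 0, 0, 0, 0, 0]), b)
        hi = ms.w_resource(np.array([0.9, 0, 0, 0, 0, 0]), b)
        assert hi > lo

    def test_w_resource_length_mismatch(self):
        with pytest.raises(ValueError):
            ms.w_resource(np.zeros(5), np.zeros(6))

    def test_w_memory_limits(self):
        assert ms.w_memory(1.0, 0.3) == pytest.approx(1.0)
        assert ms.w_memory(0.42, 1e-9) == pytest.approx(1.0, abs=1e-8)
        assert 1 - 0.8 < ms.w_memory(0.5, 0.8) <= 1.0

    def test_fixed_memory_beta0_is_expit_one(self):
        assert BETA0_FIXED_MEMORY == pytest.approx(expit(1.0))
        assert round(BETA0_FIXED_MEMORY, 4) == 0.7311

    def test_revisit_gate_closed_forms(self):
        b = np.zeros(6)
        assert ms.revisit_gate(np.zeros(6), b, 0.5) == pytest.approx(0.5)
        assert ms.revisit_gate(np.zeros(6), b, 0.3) == pytest.approx(0.3)
        # beta.r = 1 at beta0 = 0.5 -> logistic(1)
        b1 = np.array([1.0, 0, 0, 0, 0, 0])
        r1 = np.array([1.0, 0, 0, 0, 0, 0])
        assert ms.revisit_gate(r1, b1, 0.5) == pytest.approx(expit(1.0))

    def test_revisit_gate_saturates_at_beta0_one(self):
        b = np.array([-3.0, 1, 0, 0, 0, 0])
        r = np.array([2.0, -1, 0, 0, 0, 0])
        assert ms.revisit_gate(r, b, 1 - 1e-12) == pytest.approx(1.0)


class TestMemoryAttraction:
    def _map_const(self, point=(2.0, 3.0), n=30):
        cm = ms.CognitiveMap(dt_fix=4.0)
        for i in range(n):
            cm.update(point, i * 4.0)
        return cm

    def test_constant_path_attraction_one(self):
        cm = self._map_const()
        a = ms.memory_attraction((2.0, 3.0), 29 * 4.0 + 4.0, cm,
                                 mu_days=2.0, sigma_days=1.0, alpha=0.0)
        assert a == pytest.approx(1.0)

    def test_decay_e_minus_one_at_scale(self):
        cm = self._map_const(point=(0.0, 0.0))
        # query 10**alpha away from every remembered location
        a = ms.memory_attraction((2.0, 0.0), 120.0, cm, mu_days=2.0,
                                 sigma_days=1.0, alpha=np.log10(2.0))
        assert a == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_two_symmetric_lags_average(self):
        cm = ms.CognitiveMap(dt_fix=4.0)
        cm.update((0.0, 0.0), 0.0)   # lag 8 h from t=8
        cm.update((3.0, 0.0), 4.0)   # lag 4 h
        d1, d2 = 3.0, 6.0            # distances from query (6, 0)
        # mu = 6 h: lags 4 and 8 are equidistant -> equal weights
        a = ms.memory_attraction((6.0, 0.0), 8.0, cm, mu_days=6 / 24,
                                 sigma_days=4 / 24, alpha=0.0)
        expected = (np.exp(-d1) + np.exp(-d2)) / 2
        assert a == pytest.approx(expected, rel=1e-9)

    def test_no_defined_lags_raises(self):
        cm = self._map_const(n=3)
        with pytest.raises(UndefinedMemoryError):
            ms.memory_attraction((0, 0), 12.0, cm, mu_days=30.0,
                                 sigma_days=1.0, alpha=0.0)

    def test_translation_invariance(self):
        cm1 = ms.CognitiveMap(dt_fix=4.0)
        cm2 = ms.CognitiveMap(dt_fix=4.0)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, size=(10, 2))
        shift = np.array([123.4, -56.7])
        for i, p in enumerate(pts):
            cm1.update(p, i * 4.0)
            cm2.update(p + shift, i * 4.0)
        q = np.array([2.0, 2.0])
        a1 = ms.memory_attraction(q, 40.0, cm1, 0.5, 0.2, 0.0)
        a2 = ms.memory_attraction(q + shift, 40.0, cm2, 0.5, 0.2, 0.0)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_decreasing_in_distance(self):
        cm = self._map_const(point=(0.0, 0.0))
        vals = [ms.memory_attraction((d, 0.0), 120.0, cm, 2.0, 1.0, 0.0)
                for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestResourceMemoryReductions:
    def test_beta_d_zero_reduces_to_resource(self, small_landscape):
        cm = ms.CognitiveMap(dt_fix=4.0)
        rng = np.random.default_rng(4)
        for i, p in enumerate(rng.uniform(5, 15, size=(20, 2))):
            cm.update(p, i * 4.0)
        params = ms.default_strong_params("resource_memory")
        params.beta_d = 1e-12
        pt = (10.0, 10.0)
        w = ms.w_resource_memory(pt, 20 * 4.0, cm, small_landscape, params)
        r = small_landscape.covariates_at(pt)
        assert w == pytest.approx(float(ms.w_resource(r, params.beta)),
                                  rel=1e-9)

    def test_beta_zero_and_gate_open_reduces_to_memory(self, small_landscape):
        cm = ms.CognitiveMap(dt_fix=4.0)
        rng = np.random.default_rng(5)
        for i, p in enumerate(rng.uniform(5, 15, size=(20, 2))):
            cm.update(p, i * 4.0)
        params = ms.default_strong_params("resource_memory")
        params.beta = np.zeros(6)
        params.beta0 = 1 - 1e-12
        params.mu, params.sigma = 2.0, 0.5
        pt = (10.0, 10.0)
        t = 20 * 4.0
        w = ms.w_resource_memory(pt, t, cm, small_landscape, params)
        a = ms.memory_attraction(pt, t, cm, params.mu, params.sigma,
                                 params.alpha)
        assert w == pytest.approx(ms.w_memory(a, params.beta_d), rel=1e-9)


class TestFnsHat:
    def _candidate_set(self, seed=0, A=200):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=(A, 2))
        return draw_candidates(u, start=(5.0, 5.0), heading_in=0.3,
                               rho_ns=0.4, kappa=0.5, dt_hours=4.0,
                               observed=(6.2, 5.4))

    def test_w_one_equals_k_exactly(self):
        cs = self._candidate_set()
        params = ms.ParamSet(rho_ns=0.4, kappa=0.5, model="null")
        d = cs.observed - cs.start
        k = crw_density(np.hypot(*d), np.arctan2(d[1], d[0]) - 0.3,
                        0.4, 0.5, 4.0)
        assert f_ns_hat(cs, params, lambda x: 1.0) == pytest.approx(
            float(k), rel=1e-12)

    def test_scale_invariance_of_weights(self, small_landscape):
        cs = self._candidate_set()
        params = ms.default_strong_params("resource")

        def w(x):
            return float(ms.w_resource(
                small_landscape.covariates_at(x, clamp=True), params.beta))

        a = f_ns_hat(cs, params, w)
        b = f_ns_hat(cs, params, lambda x: 137.0 * w(x))
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_exhaustive_grid_small(self, small_landscape):
        # Monte-Carlo normalizer vs brute-force sum of k*W over all cells.
        # Selection on the standardized habitat fields only: raw-km
        # distance covariates give W a heavy tail that would need a much
        # larger candidate set for the same Monte-Carlo error.
        ls = small_landscape
        params = ms.default_strong_params("resource")
        params.beta = np.array([0.5, 0.0, 0.5, 0.0, 0.0, 0.0])
        rng = np.random.default_rng(11)
        u = rng.uniform(size=(20000, 2))
        start, heading = np.array([10.0, 10.0]), 0.0
        cs = draw_candidates(u, start, heading, params.rho_ns, params.kappa,
                             4.0, observed=(11.0, 10.3))

        def w(x):
            return float(ms.w_resource(ls.covariates_at(x, clamp=True),
                                       params.beta))

        estimate = f_ns_hat(cs, params, w)
        from tests._oracles import exhaustive_kw_normalizer
        X, Y = ls.cell_centers()
        pts = np.column_stack([X.ravel(), Y.ravel()])
        W_grid = np.exp(ls.covariates_at(pts) @ params.beta).reshape(X.shape)
        norm = exhaustive_kw_normalizer(ls, start, heading, params.rho_ns,
                                        params.kappa, 4.0, W_grid)
        dobs = cs.observed - start
        k_obs = float(crw_density(np.hypot(*dobs),
                                  np.arctan2(dobs[1], dobs[0]) - heading,
                                  params.rho_ns, params.kappa, 4.0))
        exact = k_obs * w(cs.observed) / norm
        assert estimate == pytest.approx(exact, rel=0.04)
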