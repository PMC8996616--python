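"""Fitting machinery: recovery on cheap cases, profile CIs, BIC selection."""

import numpy as np
import pytest

import memstep as ms
from memstep.model import (MemoryMovementModel, profile_ci, profile_interval,
                           select_models, significance_report)
from memstep.params import SIGMA_MIN, active_names, n_free_params


@pytest.fixture(scope="module")
def null_fit(null_track):
    return ms.fit_model(null_track, None, model="null")


class TestParameterCounts:
    @pytest.mark.parametrize("model,k", [("null", 4), ("resource", 10),
                                         ("memory", 8),
                                         ("resource_memory", 15)])
    def test_active_parameter_counts(self, model, k):
        assert n_free_params(model) == k
        assert len(active_names(model)) == k


class TestNullRecovery:
    def test_recovery_across_replicates(self):
        truth = ms.ParamSet(rho_ns=0.4, kappa=0.5, lambda_=0.4,
                            gamma_=0.75, model="null")
        ok = 0
        for rep in range(10):
            tr = ms.simulate_track("null", params=truth, n_steps=600,
                                   seed=500 + rep)
            res = ms.fit_model(tr, None, model="null")
            p = res.params
            if (abs(p.kappa - 0.5) <= 0.1 and abs(p.lambda_ - 0.4) <= 0.1
                    and abs(p.gamma_ - 0.75) <= 0.1
                    and abs(p.rho_ns - 0.4) / 0.4 <= 0.15):
                ok += 1
        assert ok >= 8

    def test_loglik_at_mle_beats_truth(self, null_track, null_fit):
        truth = ms.ParamSet(rho_ns=0.4, kappa=0.5, lambda_=0.4,
                            gamma_=0.75, model="null")
        mm = MemoryMovementModel(null_track, None, model="null")
        assert null_fit.loglik >= mm.loglike(truth) - 1e-3


class TestFitResult:
    def test_bic_identity(self, null_fit):
        k, n = null_fit.n_params, null_fit.n_obs
        assert null_fit.bic == pytest.approx(
            k * np.log(n) - 2 * null_fit.loglik, abs=1e-9)

    def test_sigma_never_below_bound(self, memory_track):
        res = ms.fit_model(memory_track, None, model="memory", starts=1,
                           maxiter=40, polish_maxiter=5)
        assert res.params.sigma >= SIGMA_MIN

    def test_summary_mentions_estimates(self, null_fit):
        s = null_fit.summary()
        assert "rho_ns" in s and "BIC" in s and "null" in s

    def test_stationary_fraction_from_fit(self, null_fit):
        s, n = null_fit.stationary_fraction()
        assert s + n == pytest.approx(1.0)
        assert 0.2 < s < 0.5  # generated at lambda/(lambda+gamma) = 0.348


class TestProfileLikelihood:
    def test_quadratic_matches_wald(self):
        # exactly quadratic negative log-likelihood: profile == Wald
        H = np.array([[2.0, 0.7], [0.7, 1.5]])
        x_hat = np.array([0.3, -0.2])

        def nll(x):
            d = x - x_hat
            return 0.5 * d @ H @ d

        def reopt(x, idx):
            free = 1 - idx
            # closed-form conditional minimum of the quadratic
            z = x.copy()
            z[free] = x_hat[free] - H[free, idx] / H[free, free] \
                * (x[idx] - x_hat[idx])
            return float(nll(z)), z

        thr = 1.9207
        lo, hi = profile_interval(nll, x_hat, 0, thr, reopt=reopt)
        prof_var = np.linalg.inv(H)[0, 0]  # profile curvature
        half = np.sqrt(2 * thr * prof_var)
        assert lo == pytest.approx(x_hat[0] - half, abs=1e-4)
        assert hi == pytest.approx(x_hat[0] + half, abs=1e-4)

    def test_interval_contains_mle(self, null_fit):
        lo, hi = profile_ci(null_fit, "kappa", level=0.95)
        assert lo <= null_fit.params.kappa <= hi

    def test_level_zero_degenerate(self):
        def nll(x):
            return float((x[0] - 1.0) ** 2)
        lo, hi = profile_interval(nll, np.array([1.0]), 0, 0.0)
        assert lo == hi == 1.0

    def test_open_interval_flagged_infinite(self):
        # flat objective never crosses the threshold
        def nll(x):
            return 0.0
        lo, hi = profile_interval(nll, np.array([0.0]), 0, 1.9207)
        assert np.isinf(lo) and np.isinf(hi)


class TestSignificance:
    def test_calls_from_intervals(self, null_fit):
        report = significance_report(null_fit, ci={
            "kappa": (0.1, 0.3), "lambda_": (0.4, 0.6),
            "gamma_": (0.6, 0.8), "rho_ns": (0.3, 0.5)})
        assert report["kappa"]["call"] == "above"        # vs 0
        assert report["lambda_"]["call"] == "overlaps"   # vs 0.5
        assert report["gamma_"]["call"] == "above"       # vs 0.5

    def test_alpha_reference_is_log10_rho(self, memory_track):
        res = ms.fit_model(memory_track, None, model="memory", starts=1,
                           maxiter=30, polish_maxiter=5)
        ci = {nm: (res.params.get(nm) - 0.01, res.params.get(nm) + 0.01)
              for nm in res.free_names}
        rep = significance_report(res, ci=ci)
        assert rep["alpha"]["reference"] == pytest.approx(
            np.log10(res.params.rho_ns))

    def test_missing_ci_not_assessed(self, null_fit):
        rep = significance_report(null_fit, ci={"kappa": (np.nan, np.nan)})
        assert rep["kappa"]["call"] == "not-assessed"


class TestSelection:
    def test_dbic_layout(self, small_landscape, memory_track):
        table = select_models(memory_track, small_landscape, A=20, seed=0,
                              models=("null", "memory"), starts=1,
                              maxiter=40)
        t = table.table
        assert (t["dbic"] >= 0).all()
        assert (t["dbic"] == 0).sum() == 1
        assert table.best_model == "memory"  # strong revisitation signal

    def test_tie_breaks_to_simpler_model(self):
        import pandas as pd
        from memstep.model import SelectionTable
        rows = pd.DataFrame({
            "model": ["null", "memory"], "n_params": [4, 8],
            "loglik": [-10.0, -10.0], "bic": [50.0, 50.0],
            "converged": [True, True]})
        best_bic = rows["bic"].min()
        ties = rows[rows["bic"] == best_bic]
        best = ties.sort_values("n_params").iloc[0]["model"]
        assert best == "null"

    def test_nested_models_loglik_ordering(self, small_landscape):
        p = ms.fig1_regime_params("resource_memory")
        tr = ms.simulate_track("resource_memory", params=p,
                               landscape=small_landscape, n_steps=400,
                               seed=77, training_steps=80, n_candidates=50,
                               dt=ms.FIG1_DT_HOURS)
        table = select_models(tr, small_landscape, A=20, seed=0, starts=1,
                              maxiter=60)
        ll = {r["model"]: r["loglik"] for _, r in table.table.iterrows()}
        tol = 1e-3
        assert ll["resource_memory"] >= ll["resource"] - tol
        assert ll["resource_memory"] >= ll["memory"] - tol
        assert ll["resource"] >= ll["null"] - tol
        assert ll["memory"] >= ll["null"] - tol


class TestEvaluatorConsistency:
    def test_cached_path_matches_reference(self, memory_track):
        """The tensor-cached memory bracket equals the plain per-step
        reference implementation."""
        from memstep.kernels import memory_attraction, w_memory
        from memstep.likelihood import LikelihoodEvaluator

        p = ms.fig1_regime_params("memory")
        ev = LikelihoodEvaluator(memory_track, None, A=5, seed=0)
        bracket = ev.memory_bracket(p)
        cmap = memory_track.cognitive_map()
        steps = memory_track.steps()
        em = steps[~steps["training"]].reset_index(drop=True)
        for t in [0, 10, 100, 250, 499]:
            pt = memory_track.xy[em.loc[t, "to_idx"]]
            t_h = memory_track.t_hours[em.loc[t, "to_idx"]]
            a = memory_attraction(pt, t_h, cmap, p.mu, p.sigma, p.alpha,
                                  dt_fix_hours=memory_track.dt_hours)
            assert bracket[t, 0] == pytest.approx(w_memory(a, p.beta_d),
                                                  rel=1e-5)

    def test_streaming_path_matches_cached(self, memory_track):
        from memstep.likelihood import LikelihoodEvaluator
        p = ms.fig1_regime_params("memory")
        ev = LikelihoodEvaluator(memory_track, None, A=5, seed=0)
        cached = ev.memory_bracket(p)
        streamed = ev._memory_bracket_streaming(p)
        assert np.allclose(cached, streamed, rtol=1e-5, atol=1e-7)
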