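"""Model fitting and selection: the user-facing Model/Results pair.

:class:`MemoryMovementModel` binds one animal's track (and optionally a
landscape) to one of the four movement hypotheses; ``fit()`` maximizes the
two-state HMM likelihood over an unconstrained transformed parameter
scale and returns :class:`MovementResults` carrying the MLEs, BIC,
confidence intervals (Wald by default, profile on request) and
diagnostics.  :func:`select_models` fits all four models on shared
candidate sets and ranks them by BIC.

Fitting is staged: movement parameters (rho_ns, kappa, lambda, gamma) are
first estimated under the null model from moment-based starts; the
cognition parameters are then optimized with movement held fixed (with a
small multistart over the revisitation lag mu); finally all active
parameters are polished jointly with a quasi-Newton step.  The returned
estimate is the joint MLE from the best start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .likelihood import LikelihoodEvaluator, stationary_fraction
from .params import (MU_MAX, MU_MIN, SIGMA_MIN, ParamSet, _from_unc,
                     active_names, n_free_params, unc_bounds)

__all__ = ["MemoryMovementModel", "MovementResults", "SelectionTable",
           "fit_model", "select_models", "profile_ci",
           "significance_report", "profile_interval",
           "revisitation_lag_scan"]

#: log-likelihood drop defining a 95% profile interval: chi2(1, .95) / 2.
PROFILE_THRESHOLD_95 = float(chi2.ppf(0.95, 1) / 2.0)

_PENALTY = 1e10  # objective value returned on numerical failure


def revisitation_lag_scan(track, min_days: float = 2.0,
                          max_samples: int = 400) -> pd.DataFrame:
    """Mean distance between locations separated by each lag.

    A dip at lag L means the animal tends to be near where it was L days
    earlier - the empirical fingerprint of scheduled revisitation, used to
    initialize mu.
    """
    pos, defined = track.indexed_path()
    n = len(pos)
    dt_days = track.dt_hours / 24.0
    min_lag = max(1, int(np.ceil(min_days / dt_days)))
    lags, dists = [], []
    for lag in range(min_lag, n - 1):
        a, b = pos[lag:], pos[:-lag]
        ok = defined[lag:] & defined[:-lag]
        m = int(ok.sum())
        if m < 20:
            continue
        idx = np.flatnonzero(ok)
        if m > max_samples:
            idx = idx[np.linspace(0, m - 1, max_samples).astype(int)]
        d = np.hypot(*(a[idx] - b[idx]).T)
        lags.append(lag * dt_days)
        dists.append(float(d.mean()))
    return pd.DataFrame({"lag_days": lags, "mean_distance_km": dists})


class MemoryMovementModel:
    """One track, one landscape, one movement hypothesis.

    Parameters
    ----------
    track : Track
        Must contain post-training steps (``excluded`` tracks are refused).
    landscape : Landscape, optional
        Required for the resource-bearing models.
    model : {"null", "resource", "memory", "resource_memory"}
    seasonal : bool
        Mask resource covariates outside their availability windows.
    A : int
        Available steps per observed step (default 50).
    seed : int
        Candidate-uniform seed; models fitted with the same track/A/seed
        share identical candidate randomness.
    """

    def __init__(self, track, landscape=None, model: str = "null",
                 seasonal: bool = False, A: int = 50, seed: int = 0,
                 evaluator: LikelihoodEvaluator | None = None):
        if track.excluded:
            raise ValueError(
                f"track {track.animal_id} is excluded (no post-training data)")
        if model in ("resource", "resource_memory") and landscape is None:
            raise ValueError(f"model {model!r} requires a landscape")
        self.track = track
        self.landscape = landscape
        self.model = model
        self.seasonal = bool(seasonal)
        self.evaluator = evaluator if evaluator is not None else \
            LikelihoodEvaluator(track, landscape, A=A, seed=seed)
        self._nll_evals = 0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, landscape=None, **kw):
        from .track import Track
        return cls(Track.from_dataframe(df), landscape=landscape, **kw)

    # -- likelihood ------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.evaluator.n_obs

    def loglike(self, params: ParamSet) -> float:
        return self.evaluator.loglik(params)

    def _template(self) -> ParamSet:
        P = self.landscape.n_layers if self.landscape is not None else 6
        return ParamSet(beta=np.zeros(P), model=self.model,
                        seasonal=self.seasonal)

    def _nll_over(self, names: list[str], base: ParamSet):
        """Negative log-likelihood as a function of the transformed
        coordinates of ``names``, other parameters held at ``base``."""
        def nll(vec: np.ndarray) -> float:
            self._nll_evals += 1
            p = base.copy()
            for nm, v in zip(names, vec):
                p.set(nm, _from_unc(nm, float(v)))
            try:
                ll = self.loglike(p)
            except (ValueError, FloatingPointError):
                return _PENALTY
            return -ll if np.isfinite(ll) else _PENALTY
        return nll

    def _optimize(self, names: list[str], start: ParamSet,
                  maxiter: int = 200):
        nll = self._nll_over(names, start)
        x0 = np.array([_to_vec(start, nm) for nm in names])
        bounds = [unc_bounds(nm) for nm in names]
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter,
                                         "maxfun": 40 * maxiter,
                                         "eps": 1e-4})
        fitted = start.copy()
        for nm, v in zip(names, res.x):
            fitted.set(nm, _from_unc(nm, float(v)))
        return fitted, float(res.fun), res

    # -- starts ----------------------------------------------------------
    def _moment_start(self) -> ParamSet:
        p = self._template()
        lens = self.evaluator.obs_len
        short = lens < 0.09  # ~3x the stationary mean step
        moving = lens[~short]
        if len(moving):
            p.rho_ns = float(np.clip(moving.mean() / self.track.dt_hours,
                                     0.01, 10.0))
        turns = self.evaluator.obs_turn[self.evaluator.hd & ~short]
        if len(turns):
            R = float(np.hypot(np.cos(turns).mean(), np.sin(turns).mean()))
            p.kappa = float(np.clip(R, 0.02, 0.9))
        if len(short) > 1:
            s0, s1 = short[:-1], short[1:]
            if s0.sum() > 0:
                p.lambda_ = float(np.clip((s0 & s1).sum() / s0.sum(),
                                          0.05, 0.95))
            if (~s0).sum() > 0:
                p.gamma_ = float(np.clip((~s0 & ~s1).sum() / (~s0).sum(),
                                         0.05, 0.95))
        p.alpha = float(np.log10(max(lens.mean(), 1e-3)))
        p.sigma = 10.0
        p.beta_d = 0.7
        p.beta0 = 0.5
        p.beta = np.zeros_like(p.beta)
        return p

    def _mu_starts(self, n: int) -> list[float]:
        """Candidate revisitation lags: the most prominent dips of the
        lag-distance scan (plus the circannual lag when the track is long
        enough), each a separate optimization start."""
        from scipy.signal import find_peaks

        span_days = float(self.track.t_hours[-1]) / 24.0
        scan = revisitation_lag_scan(self.track)
        out: list[float] = []
        if len(scan) > 10:
            d = scan["mean_distance_km"].to_numpy()
            lag = scan["lag_days"].to_numpy()
            # smooth lightly, then rank local minima by prominence
            w = max(3, int(1.0 / max(lag[1] - lag[0], 1e-6)))
            ds = np.convolve(d, np.ones(w) / w, mode="same")
            peaks, props = find_peaks(-ds, prominence=0.02 * np.ptp(ds))
            order = np.argsort(props["prominences"])[::-1]
            for i in order[:max(n, 2)]:
                out.append(float(np.clip(lag[peaks[i]],
                                         MU_MIN + 0.5, MU_MAX - 0.5)))
            gmin = float(np.clip(lag[int(np.argmin(ds))],
                                 MU_MIN + 0.5, MU_MAX - 0.5))
            if all(abs(gmin - v) > 2.0 for v in out):
                out.append(gmin)
        if span_days > 380:
            out.append(365.0)
        out = [v for i, v in enumerate(out)
               if all(abs(v - u) > 2.0 for u in out[:i])]
        return out[:n] or [min(30.0, max(MU_MIN + 0.5, span_days / 3))]

    def _mu_grid_starts(self, start: ParamSet, n: int) -> list[float]:
        """Rank candidate revisitation lags by actual likelihood.

        Candidates are the prominent dips of the lag-distance scan plus a
        coarse geometric grid over the feasible lag range (and the
        circannual lag when the track spans it); the best ``n`` by
        log-likelihood (other parameters at their starting values) seed
        the staged optimization.
        """
        span_days = float(self.track.t_hours[-1]) / 24.0
        cand = list(self._mu_starts(3))
        hi = min(MU_MAX - 5.0, max(span_days - 20.0, MU_MIN + 10.0))
        cand += list(np.geomspace(MU_MIN + 2.0, hi, 8))
        cand = sorted(cand)
        keep: list[float] = []
        for v in cand:
            if all(abs(v - u) > 0.12 * max(v, u) for u in keep):
                keep.append(v)
        scored = []
        for mu0 in keep:
            p = start.copy()
            p.mu = mu0
            p.sigma = float(np.clip(mu0 / 10.0, SIGMA_MIN + 2.0, 12.0))
            try:
                ll = self.loglike(p)
            except (ValueError, FloatingPointError):
                ll = -np.inf
            scored.append((ll, mu0))
        scored.sort(reverse=True)
        return [mu for _, mu in scored[:n]]

    # -- fit ---------------------------------------------------------------
    def fit(self, starts: int | None = None, maxiter: int = 100,
            polish_maxiter: int = 15,
            warm: dict | None = None) -> "MovementResults":
        """Maximize the likelihood; deterministic given the model's seed.

        ``starts`` bounds the multistart over the revisitation lag mu
        (memory-bearing models; default 2).  ``warm`` may supply already-
        fitted simpler models ({"null": ParamSet, "resource": ParamSet})
        to skip the corresponding initialization stages - used by
        :func:`select_models`, which fits the nested family in order.
        Non-convergence across all starts returns the best attempt with
        ``converged=False``.
        """
        self._nll_evals = 0
        warm = warm or {}
        movement = ["rho_ns", "kappa", "lambda_", "gamma_"]

        if "null" in warm:
            null_fit = warm["null"].copy()
            null_res = None
            if self.model == "null":
                nll = -self.loglike(null_fit)
                return self._results(null_fit, -nll, None)
        else:
            null_base = self._moment_start()
            null_base.model = "null"
            null_fit, null_nll, null_res = self._optimize(
                movement, null_base, maxiter)
            if self.model == "null":
                return self._results(null_fit, -null_nll, null_res)

        start = null_fit.copy()
        start.model = self.model
        start.seasonal = self.seasonal
        start.beta = np.zeros_like(start.beta)
        start.beta_d, start.beta0 = 0.7, 0.5
        start.alpha = float(np.log10(max(self.evaluator.obs_len.mean(),
                                         1e-3)))

        if self.model == "resource":
            names = active_names("resource", start.P)
            fitted, nll, res = self._optimize(names, start, maxiter)
            return self._results(fitted, -nll, res)

        # memory-bearing models: multistart over mu, staged then joint
        stage_names = (["beta0"] if self.model == "resource_memory" else []) \
            + ["beta_d", "mu", "sigma", "alpha"]
        if self.model == "resource_memory":
            if "resource" in warm:
                res_fit = warm["resource"].copy()
            else:
                res_names = active_names("resource", start.P)
                res_start = start.copy()
                res_start.model = "resource"
                res_fit, _, _ = self._optimize(res_names, res_start,
                                               maxiter)
            start = res_fit.copy()
            start.model = "resource_memory"
            start.seasonal = self.seasonal
            start.beta_d, start.beta0 = 0.7, 0.5
            start.alpha = float(np.log10(max(self.evaluator.obs_len.mean(),
                                             1e-3)))

        n_starts = 2 if starts is None else max(int(starts), 1)
        best = None
        # coarse-to-fine: the staged search samples the lag grid daily
        # (Gaussian weights renormalized); the joint polish and every
        # reported likelihood use the exact fix-grid lags
        daily = max(1, int(round(24.0 / self.track.dt_hours)))
        self.evaluator.lag_stride = daily
        try:
            stage_starts = []
            if self.model == "resource_memory" and "memory" in warm:
                m = warm["memory"]
                # the memory-only fit's schedule on top of the resource fit
                s = start.copy()
                s.beta_d, s.mu, s.sigma, s.alpha = (m.beta_d, m.mu,
                                                    m.sigma, m.alpha)
                stage_starts.append(s)
                # the exact memory-only embedding (beta = 0, open gate):
                # guarantees the nested-likelihood inequality
                s2 = m.copy()
                s2.model = "resource_memory"
                s2.seasonal = self.seasonal
                s2.beta = np.zeros_like(start.beta)
                s2.beta0 = 1.0 - 1e-9
                stage_starts.append(s2)
            for mu0 in self._mu_grid_starts(start, n_starts):
                s = start.copy()
                s.mu = mu0
                s.sigma = float(np.clip(mu0 / 10.0, SIGMA_MIN + 2.0, 12.0))
                stage_starts.append(s)
            staged_results = []
            for s in stage_starts:
                staged, _, _ = self._optimize(stage_names, s,
                                              min(maxiter, 30))
                staged_results.append(staged)
        finally:
            self.evaluator.lag_stride = 1
        # rank staged endpoints by the exact (unstrided) likelihood
        for staged in staged_results:
            nll1 = -self.loglike(staged)
            if best is None or nll1 < best[1]:
                best = (staged, nll1)
        best_exact = best[1]
        joint_names = active_names(self.model, start.P)
        fitted, nll, res = self._optimize(joint_names, best[0],
                                          polish_maxiter)
        if nll > best_exact:  # polish should not move uphill
            fitted, nll = best[0], best_exact
        return self._results(fitted, -nll, res)

    def _results(self, params: ParamSet, loglik: float, opt_res):
        k = n_free_params(self.model, params.P)
        grad_norm = float(np.max(np.abs(opt_res.jac))) \
            if getattr(opt_res, "jac", None) is not None else np.nan
        return MovementResults(
            model=self.model, seasonal=self.seasonal, params=params,
            loglik=float(loglik), n_obs=self.n_obs, n_params=k,
            bic=float(k * np.log(self.n_obs) - 2.0 * loglik),
            converged=(bool(opt_res.success) if opt_res is not None
                       else True) or grad_norm < 1e-3,
            diagnostics={"nit": int(getattr(opt_res, "nit", -1)),
                         "nfev": self._nll_evals,
                         "grad_norm": grad_norm,
                         "message": str(getattr(opt_res, "message", ""))},
            _model=self)


def _to_vec(p: ParamSet, name: str) -> float:
    from .params import _to_unc
    return _to_unc(name, p.get(name))


# --------------------------------------------------------------------------
# results


@dataclass
class MovementResults:
    """MLEs and inference summaries for one fitted movement model."""

    model: str
    seasonal: bool
    params: ParamSet
    loglik: float
    n_obs: int
    n_params: int
    bic: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    _model: "MemoryMovementModel | None" = None

    @property
    def free_names(self) -> list[str]:
        return active_names(self.model, self.params.P)

    def stationary_fraction(self) -> tuple[float, float]:
        """(stationary, non-stationary) occupancy, lambda/(lambda+gamma)."""
        return stationary_fraction(self.params.lambda_, self.params.gamma_)

    # -- confidence intervals ------------------------------------------
    def conf_int(self, method: str = "wald", names: list[str] | None = None,
                 level: float = 0.95) -> dict:
        """95% (by default) intervals per free parameter, natural scale.

        ``wald``: from the numeric Hessian on the transformed scale,
        endpoints back-transformed.  ``profile``: likelihood profiling
        (slower; re-optimizes the other parameters at each probe).
        """
        names = names or self.free_names
        if method == "wald":
            out = self._wald_ci(level)
        elif method == "profile":
            out = {nm: profile_ci(self, nm, level) for nm in names}
        else:
            raise ValueError(f"unknown CI method {method!r}")
        out = {nm: out[nm] for nm in names if nm in out}
        self.ci.update(out)
        return out

    def _wald_ci(self, level: float) -> dict:
        if self._model is None:
            raise ValueError("results are detached from their model")
        names = self.free_names
        nll = self._model._nll_over(names, self.params)
        x0 = np.array([_to_vec(self.params, nm) for nm in names])
        H = _numeric_hessian(nll, x0)
        try:
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        out = {}
        for i, nm in enumerate(names):
            lo = _from_unc(nm, x0[i] - z * se[i]) if np.isfinite(se[i]) else np.nan
            hi = _from_unc(nm, x0[i] + z * se[i]) if np.isfinite(se[i]) else np.nan
            out[nm] = (lo, hi)
        return out

    def significance(self, ci: dict | None = None) -> dict:
        return significance_report(self, ci=ci)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        sf = self.stationary_fraction()
        lines = [
            "Memory-informed movement model".center(62),
            "=" * 62,
            f"Model:            {self.model:<22} Seasonal: {self.seasonal}",
            f"No. observations: {self.n_obs:<22} Params:   {self.n_params}",
            f"Log-likelihood:   {self.loglik:<22.3f} BIC:      {self.bic:.3f}",
            f"Converged:        {str(self.converged):<22} "
            f"Stationary occupancy: {sf[0]:.3f}",
            "-" * 62,
            f"{'parameter':<12}{'estimate':>12}{'ci_low':>12}{'ci_high':>12}",
        ]
        for nm in self.free_names:
            lo, hi = self.ci.get(nm, (np.nan, np.nan))
            lines.append(f"{nm:<12}{self.params.get(nm):>12.4f}"
                         f"{lo:>12.4f}{hi:>12.4f}")
        if self.model == "memory":
            lines.append(f"{'beta0':<12}{self.params.beta0:>12.4f}"
                         f"{'(fixed)':>12}{'':>12}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def to_series(self) -> pd.Series:
        d = self.params.as_dict()
        d.update(loglik=self.loglik, bic=self.bic, n_obs=self.n_obs,
                 n_params=self.n_params, converged=self.converged)
        return pd.Series(d)


# --------------------------------------------------------------------------
# profile likelihood


def profile_interval(objective, x0: np.ndarray, index: int,
                     threshold: float, xtol: float = 1e-5,
                     max_expand: int = 40, reopt=None):
    """Generic profile-likelihood interval on the working scale.

    ``objective`` maps a full coordinate vector to a negative
    log-likelihood; ``x0`` is its minimizer.  The profile at a fixed value
    v of coordinate ``index`` re-minimizes over the remaining coordinates
    (``reopt``; identity for a 1-D problem).  Returns (lo, hi) where the
    profiled objective exceeds its minimum by ``threshold``; an endpoint
    that never crosses within the expansion range is returned as +/-inf
    (open-ended).
    """
    x0 = np.asarray(x0, dtype=float)
    f0 = float(objective(x0))
    if threshold <= 0:
        return float(x0[index]), float(x0[index])

    others = [j for j in range(len(x0)) if j != index]

    def profile(v: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        x = warm.copy()
        x[index] = v
        if not others or reopt is None:
            return float(objective(x)), x
        return reopt(x, index)

    out = []
    for sign in (-1.0, +1.0):
        h = max(0.25, 0.1 * abs(x0[index]))
        warm = x0.copy()
        lo_v, lo_f = float(x0[index]), f0
        bound = None
        for _ in range(max_expand):
            v = float(x0[index]) + sign * h
            fv, warm = profile(v, warm)
            if fv - f0 >= threshold:
                bound = (lo_v, v) if sign > 0 else (v, lo_v)
                break
            lo_v, lo_f = v, fv
            h *= 1.8
        if bound is None:
            out.append(sign * np.inf)
            continue

        def g(v, _warm=[warm]):
            fv, _warm[0] = profile(float(v), _warm[0])
            return fv - f0 - threshold

        root = optimize.brentq(g, bound[0], bound[1], xtol=xtol)
        out.append(float(root))
    return out[0], out[1]


def profile_ci(results: MovementResults, name: str,
               level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval for one parameter, natural scale.

    The profile deviance threshold is chi2_1(level)/2 nats below the
    maximum; the search runs on the transformed scale and endpoints are
    back-transformed.  Infinite endpoints flag intervals that never cross
    the threshold inside the parameter bounds (open-ended).
    """
    if results._model is None:
        raise ValueError("results are detached from their model")
    names = results.free_names
    if name not in names:
        raise ValueError(f"{name!r} is not a free parameter of {results.model}")
    index = names.index(name)
    nll = results._model._nll_over(names, results.params)
    x0 = np.array([_to_vec(results.params, nm) for nm in names])
    threshold = float(chi2.ppf(level, 1) / 2.0)

    def reopt(x, idx):
        free = [j for j in range(len(x)) if j != idx]

        def sub(y):
            z = x.copy()
            z[free] = y
            return nll(z)

        r = optimize.minimize(sub, x[free], method="L-BFGS-B",
                              options={"maxiter": 60})
        z = x.copy()
        z[free] = r.x
        return float(r.fun), z

    lo_t, hi_t = profile_interval(nll, x0, index, threshold,
                                  reopt=reopt if len(names) > 1 else None)
    lo = _from_unc(name, lo_t) if np.isfinite(lo_t) else _bound(name, -1)
    hi = _from_unc(name, hi_t) if np.isfinite(hi_t) else _bound(name, +1)
    return lo, hi


def _bound(name: str, side: int) -> float:
    """Natural-scale bound reached when a profile never crosses (the
    interval is one-sided / open-ended there)."""
    bounds = {"rho_ns": (0.0, np.inf), "kappa": (0.0, 1.0),
              "beta0": (0.0, 1.0), "beta_d": (0.0, 1.0),
              "lambda_": (0.0, 1.0), "gamma_": (0.0, 1.0),
              "sigma": (SIGMA_MIN, np.inf), "mu": (MU_MIN, MU_MAX)}
    lo, hi = bounds.get(name, (-np.inf, np.inf))
    return lo if side < 0 else hi


def _numeric_hessian(f, x0: np.ndarray, h: float = 0.02) -> np.ndarray:
    """Central-difference Hessian with a deliberately wide step: raster
    covariates are piecewise constant in the candidate endpoints, so the
    likelihood has micro-discontinuities in (rho_ns, kappa); a step much
    larger than the cell-crossing scale averages over them."""
    n = len(x0)
    H = np.zeros((n, n))
    hs = h * np.maximum(1.0, np.abs(x0))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n); ei[i] = hs[i]
        fpp = f(x0 + ei); fmm = f(x0 - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / hs[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = hs[j]
            fpj = f(x0 + ei + ej); fmj = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpj - fpp - f(x0 + ej) + 2 * f0
                                 - f(x0 - ei) - f(x0 - ej) + fmj) \
                / (2 * hs[i] * hs[j])
    return H


# --------------------------------------------------------------------------
# significance conventions


def significance_report(results: MovementResults,
                        ci: dict | None = None) -> dict:
    """Per-parameter significance calls against the conventional reference
    values: kappa and each beta_p against 0; beta_d and beta0 against 0.5;
    lambda and gamma against 0.5; alpha against log10(rho_ns_hat), the
    scale at which the decay at one mean step equals e^-1.
    """
    if ci is None:
        ci = results.ci or results.conf_int()
    refs = {"kappa": 0.0, "beta_d": 0.5, "beta0": 0.5,
            "lambda_": 0.5, "gamma_": 0.5,
            "alpha": float(np.log10(results.params.rho_ns))}
    for p in range(1, results.params.P + 1):
        refs[f"beta_{p}"] = 0.0
    out = {}
    for nm, ref in refs.items():
        if nm not in results.free_names:
            continue
        if nm not in ci or not np.all(np.isfinite(ci[nm])):
            out[nm] = {"reference": ref, "call": "not-assessed"}
            continue
        lo, hi = ci[nm]
        call = "above" if lo > ref else "below" if hi < ref else "overlaps"
        out[nm] = {"reference": ref, "call": call,
                   "ci": (float(lo), float(hi))}
    return out


# --------------------------------------------------------------------------
# model selection


@dataclass
class SelectionTable:
    """BIC comparison of the four movement hypotheses for one animal."""

    table: pd.DataFrame
    best_model: str
    runners_within_2: list[str]
    results: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def select_models(track, landscape, seasonal: bool = False, A: int = 50,
                  seed: int = 0, models=("null", "resource", "memory",
                                         "resource_memory"),
                  starts: int | None = None, maxiter: int = 100,
                  polish_maxiter: int = 15) -> SelectionTable:
    """Fit the candidate models on shared candidate sets and rank by BIC.

    dBIC is the difference from the best model; runners with dBIC < 2 are
    flagged as comparably supported.  Exact BIC ties break toward the
    model with fewer parameters.  A non-converged fit is kept in the
    table and flagged, never dropped.
    """
    evaluator = LikelihoodEvaluator(track, landscape, A=A, seed=seed)
    fits: dict[str, MovementResults] = {}
    warm: dict = {}
    for m in models:
        mm = MemoryMovementModel(track, landscape, model=m,
                                 seasonal=seasonal, evaluator=evaluator)
        fits[m] = mm.fit(starts=starts, maxiter=maxiter,
                         polish_maxiter=polish_maxiter, warm=dict(warm))
        if m in ("null", "resource", "memory"):
            warm[m] = fits[m].params
    rows = pd.DataFrame([{
        "model": m, "n_params": r.n_params, "loglik": r.loglik,
        "bic": r.bic, "converged": r.converged} for m, r in fits.items()])
    best_bic = rows["bic"].min()
    ties = rows[rows["bic"] == best_bic]
    best = ties.sort_values("n_params").iloc[0]["model"]
    rows["dbic"] = rows["bic"] - best_bic
    runners = [m for m, d in zip(rows["model"], rows["dbic"])
               if m != best and d < 2.0]
    return SelectionTable(table=rows, best_model=str(best),
                          runners_within_2=runners, results=fits)


def fit_model(track, landscape=None, model: str = "null",
              seasonal: bool = False, A: int = 50, seed: int = 0,
              starts: int | None = None, maxiter: int = 100,
              polish_maxiter: int = 15) -> MovementResults:
    """Functional wrapper: build the model object and fit it."""
    mm = MemoryMovementModel(track, landscape, model=model,
                             seasonal=seasonal, A=A, seed=seed)
    return mm.fit(starts=starts, maxiter=maxiter,
                  polish_maxiter=polish_maxiter)
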