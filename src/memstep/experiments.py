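"""Canned simulation experiments: recovery, identification, oracle checks.

These are the package's standard self-validation studies:

- :func:`mu_recovery_experiment` - can the memory-only fit recover the
  revisitation lag mu from two simulated collar-years?
- :func:`model_identification_experiment` - does BIC select the
  generating hypothesis for tracks simulated under each of the four
  behavioural regimes?
- :func:`fns_normalization_check` - Monte-Carlo step-density normalizer
  vs an exhaustive integral over every landscape cell.
- :func:`forward_enumeration_check` - HMM forward log-likelihood vs a
  brute-force sum over all 2^T state sequences.
- :func:`seasonal_invariance_check` - resource-free models must be
  bit-identical with and without seasonal resource masking.
- :func:`reduction_identity_check` - limiting-case algebra of the
  weighting functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kernels import crw_density, draw_candidates, f_ns_hat
from .landscape import default_bear_landscape, generate_random_landscape
from .likelihood import (LikelihoodEvaluator, enumerate_loglik,
                         forward_from_emissions)
from .model import MemoryMovementModel, select_models
from .params import ParamSet
from .simulate import (FIG1_DT_HOURS, default_strong_params,
                       fig1_regime_params, generate_study, simulate_track)

__all__ = ["mu_recovery_experiment", "model_identification_experiment",
           "fns_normalization_check", "forward_enumeration_check",
           "seasonal_invariance_check", "reduction_identity_check"]

MODELS = ("null", "resource", "memory", "resource_memory")


# ----------------------------------------------------------------------
# parameter recovery

def mu_recovery_experiment(seed: int, n_replicates: int = 10,
                           n_years: int = 2, mu: float = 100.0,
                           sigma: float = 5.0, beta_d: float = 0.95,
                           verbose: bool = False) -> pd.DataFrame:
    """Simulate ``n_replicates`` two-year memory-only collar deployments
    (first year training) and refit the memory-only model to each.

    Returns one row per replicate with the true and estimated schedule.
    """
    truth = default_strong_params("memory")
    truth.mu, truth.sigma, truth.beta_d = mu, sigma, beta_d
    rows = []
    for rep in range(n_replicates):
        track = generate_study(seed=seed * 1009 + rep, n_animals=1,
                               n_years=n_years, landscape=None,
                               params_per_animal=[truth], model="memory")[0]
        mm = MemoryMovementModel(track, None, model="memory", seed=seed)
        res = mm.fit(starts=3)
        rows.append({
            "replicate": rep, "mu_true": mu, "mu_hat": res.params.mu,
            "sigma_hat": res.params.sigma, "beta_d_hat": res.params.beta_d,
            "alpha_hat": res.params.alpha, "loglik": res.loglik,
            "converged": res.converged,
            "abs_error_days": abs(res.params.mu - mu),
        })
        if verbose:
            print(f"  replicate {rep}: mu_hat = {res.params.mu:.1f} d",
                  flush=True)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# model identification

def model_identification_experiment(seed: int, n_replicates: int = 10,
                                    n_steps: int = 600,
                                    models=MODELS,
                                    verbose: bool = False) -> pd.DataFrame:
    """Simulate each behavioural regime and ask BIC which hypothesis
    generated it.

    Each replicate simulates a ``n_steps``-step track under the regime's
    strong-effect parameters (first 100 fixes memory-seeding training)
    and fits all four models on shared candidate sets.
    """
    landscape = default_bear_landscape(seed=seed, n_rows=120, n_cols=120,
                                       cell_size=0.5)
    rows = []
    for gen in models:
        for rep in range(n_replicates):
            p = fig1_regime_params(gen)
            track = simulate_track(gen, params=p, landscape=landscape,
                                   n_steps=n_steps,
                                   seed=seed * 7919 + 131 * rep +
                                   MODELS.index(gen),
                                   training_steps=100, dt=FIG1_DT_HOURS)
            table = select_models(track, landscape, A=50, seed=seed,
                                  starts=1, maxiter=40, polish_maxiter=6)
            rows.append({
                "generating": gen, "replicate": rep,
                "best": table.best_model,
                "correct": table.best_model == gen,
                "dbic_runner": float(
                    table.table.loc[table.table["dbic"] > 0, "dbic"].min()),
            })
            if verbose:
                print(f"  {gen} rep {rep}: best = {table.best_model}",
                      flush=True)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# oracle: Monte-Carlo normalizer vs exhaustive grid

def _exhaustive_normalizer(landscape, start, heading_in, rho_ns, kappa,
                           dt_hours, weight_grid, subdivide=3):
    """integral(k * W) over the grid; W piecewise constant per cell, k
    integrated by midpoint subdivision with adaptive quadrature on the
    cell containing the step origin (integrable 1/length singularity)."""
    start = np.asarray(start, dtype=float)
    a = landscape.cell_size
    x0, y0 = landscape.origin
    row0, col0 = landscape.cell_index([start])
    row0, col0 = int(row0[0]), int(col0[0])
    offs = (np.arange(subdivide) + 0.5) / subdivide * a
    xs = x0 + np.arange(landscape.n_cols)[:, None] * a + offs[None, :]
    ys = y0 + np.arange(landscape.n_rows)[:, None] * a + offs[None, :]
    X, Y = np.meshgrid(xs.ravel(), ys.ravel())
    lens = np.hypot(X - start[0], Y - start[1])
    turns = np.arctan2(Y - start[1], X - start[0]) - heading_in
    k = crw_density(lens, turns, rho_ns, kappa, dt_hours)
    k = k.reshape(landscape.n_rows, subdivide, landscape.n_cols, subdivide)
    k_cell = k.sum(axis=(1, 3)) * (a / subdivide) ** 2
    total = float((k_cell * weight_grid).sum())
    # the cell containing the origin has an integrable 1/length
    # singularity: integrate it exactly in polar coordinates, where the
    # Jacobian cancels and the radial integral is the exponential CDF
    from .kernels import wrapped_cauchy_pdf
    mean_len = rho_ns * dt_hours
    xl, xr = x0 + col0 * a - start[0], x0 + (col0 + 1) * a - start[0]
    yb, yt = y0 + row0 * a - start[1], y0 + (row0 + 1) * a - start[1]
    n_theta = 4000
    thetas = -np.pi + (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)

    def ray_to_box(theta):
        c, s = np.cos(theta), np.sin(theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            tx = np.where(c > 0, xr / c, np.where(c < 0, xl / c, np.inf))
            ty = np.where(s > 0, yt / s, np.where(s < 0, yb / s, np.inf))
        return np.minimum(tx, ty)

    R = ray_to_box(thetas)
    ang = wrapped_cauchy_pdf(thetas - heading_in, kappa)
    radial = 1.0 - np.exp(-np.maximum(R, 0.0) / mean_len)
    exact = float((ang * radial).sum()) * (2 * np.pi / n_theta)
    total += (exact - k_cell[row0, col0]) * weight_grid[row0, col0]
    return total


def fns_normalization_check(seed: int, A_values=(100, 1000, 10000),
                            n_eval_steps: int = 20) -> pd.DataFrame:
    """Mean absolute relative error of the Monte-Carlo normalized step
    density against the exhaustive-grid integral on a 50 x 50 landscape,
    per candidate-set size."""
    ls = generate_random_landscape(
        seed, 50, 50, 0.5,
        [{"name": "a", "kind": "smooth", "smoothness": 4},
         {"name": "b", "kind": "smooth", "smoothness": 4}])
    params = ParamSet(rho_ns=0.4, kappa=0.4, beta=np.array([0.5, 0.5]),
                      model="resource")
    X, Y = ls.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    W_grid = np.exp(ls.covariates_at(pts) @ params.beta).reshape(X.shape)

    def w(x):
        return float(np.exp(ls.covariates_at(x, clamp=True) @ params.beta))

    rng = np.random.default_rng(seed + 1)
    rows = []
    evals = []
    for _ in range(n_eval_steps):
        start = rng.uniform(8, 17, size=2)
        heading = rng.uniform(-np.pi, np.pi)
        obs = start + rng.uniform(-2, 2, size=2)
        norm = _exhaustive_normalizer(ls, start, heading, params.rho_ns,
                                      params.kappa, 4.0, W_grid)
        d = obs - start
        k_obs = float(crw_density(np.hypot(*d),
                                  np.arctan2(d[1], d[0]) - heading,
                                  params.rho_ns, params.kappa, 4.0))
        exact = k_obs * w(obs) / norm
        evals.append((start, heading, obs, exact))
    for A in A_values:
        errs = []
        for i, (start, heading, obs, exact) in enumerate(evals):
            u = np.random.default_rng(seed + 100 + i).uniform(size=(A, 2))
            cs = draw_candidates(u, start, heading, params.rho_ns,
                                 params.kappa, 4.0, observed=obs)
            est = f_ns_hat(cs, params, w)
            errs.append(abs(est - exact) / exact)
        rows.append({"A": A, "mean_rel_error": float(np.mean(errs)),
                     "max_rel_error": float(np.max(errs))})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# oracle: forward vs enumeration

def forward_enumeration_check(seed: int, T: int = 8) -> float:
    """Max |forward - enumeration| log-likelihood difference over a few
    random emission matrices (nats)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(5):
        log_em = np.log(rng.uniform(0.02, 3.0, size=(T, 2)))
        seg = np.zeros(T, dtype=bool)
        seg[0] = True
        if rng.random() < 0.5:
            seg[T // 2] = True
        lam, gam = rng.uniform(0.2, 0.8, size=2)
        a = forward_from_emissions(log_em, seg, lam, gam)
        b = enumerate_loglik(log_em, seg, lam, gam)
        worst = max(worst, abs(a - b))
    return worst


# ----------------------------------------------------------------------
# seasonal invariance

def seasonal_invariance_check(seed: int) -> dict:
    """Fit-path invariance of resource-free models to seasonal masking.

    Simulates one two-year track, fits null and memory-only models with
    seasonal masking on and off (same candidate sets), and returns the
    BIC differences (must be exactly 0) plus the resource-model
    log-likelihood shift (must be nonzero: the mask really acts).
    """
    ls = default_bear_landscape(seed=seed, n_rows=80, n_cols=80,
                                cell_size=0.5)
    truth = fig1_regime_params("resource_memory")
    # start in July so the track straddles the berry/riparian windows
    track = simulate_track("resource_memory", params=truth, landscape=ls,
                           n_steps=600, seed=seed, training_steps=100,
                           dt=FIG1_DT_HOURS,
                           start_time="2003-07-01T00:00:00")
    out = {}
    for model in ("null", "memory"):
        fits = []
        for seasonal in (False, True):
            mm = MemoryMovementModel(track, ls, model=model,
                                     seasonal=seasonal, seed=seed)
            fits.append(mm.fit(starts=1, maxiter=40, polish_maxiter=5))
        out[f"{model}_bic_diff"] = fits[1].bic - fits[0].bic
    ev = LikelihoodEvaluator(track, ls, A=50, seed=seed)
    p = default_strong_params("resource")
    p_sea = p.copy()
    p_sea.seasonal = True
    out["resource_loglik_shift"] = abs(ev.loglik(p_sea) - ev.loglik(p))
    return out


# ----------------------------------------------------------------------
# reduction identities

def reduction_identity_check(seed: int = 0) -> dict:
    """Machine-precision limiting cases of the weighting functions:
    beta_d -> 0 collapses W_RM to W_R and W_M to 1; W = 1 makes the
    normalized step density equal the kernel k."""
    from .cognitive import CognitiveMap
    from .kernels import (memory_attraction, w_memory, w_resource,
                          w_resource_memory)

    ls = default_bear_landscape(seed=seed, n_rows=40, n_cols=40,
                                cell_size=0.5)
    rng = np.random.default_rng(seed)
    cmap = CognitiveMap(dt_fix=4.0)
    for i, p in enumerate(ls.center() + rng.uniform(-4, 4, size=(30, 2))):
        cmap.update(p, i * 4.0)
    t = 30 * 4.0
    point = ls.center() + np.array([1.0, -0.5])

    params = default_strong_params("resource_memory")
    params.mu, params.sigma = 2.0, 0.5
    p0 = params.copy()
    p0.beta_d = 1e-15
    wr = float(w_resource(ls.covariates_at(point, clamp=True), params.beta))
    err_rm = abs(w_resource_memory(point, t, cmap, ls, p0) - wr) / wr

    a = memory_attraction(point, t, cmap, params.mu, params.sigma,
                          params.alpha)
    err_m = abs(w_memory(a, 1e-15) - 1.0)

    u = np.random.default_rng(seed + 1).uniform(size=(200, 2))
    cs = draw_candidates(u, ls.center(), 0.2, 0.4, 0.3, 4.0,
                         observed=point)
    d = cs.observed - cs.start
    k = float(crw_density(np.hypot(*d), np.arctan2(d[1], d[0]) - 0.2,
                          0.4, 0.3, 4.0))
    null_params = ParamSet(rho_ns=0.4, kappa=0.3, model="null")
    err_fns = abs(f_ns_hat(cs, null_params, lambda x: 1.0) - k) / k
    return {"w_rm_to_w_r": err_rm, "w_m_to_one": err_m,
            "f_ns_to_k": err_fns}
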