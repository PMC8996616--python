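"""Two-state HMM likelihood for the four movement models.

States are *stationary* (resting; half-normal step lengths with mean 30 m,
uniform heading) and *non-stationary* (moving; the step-selection density
f_ns).  Transition matrix [[lambda, 1-lambda], [1-gamma, gamma]]; the
initial distribution is the chain's stationary distribution.  The forward
recursion is scaled, restarts at every burst boundary (collar gap /
denning), and skips training-year steps entirely - those fixes seed the
cognitive map but contribute no emission terms.

The memory weighting inner loop (per step x candidate x lag) is compiled
with numba; :mod:`memstep.kernels` holds the plain reference
implementations the tests check it against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import DegenerateWeightsError
from .kernels import (LAG_TRUNCATION_SD, crw_log_density,
                      stationary_log_density, wrapped_cauchy_ppf)

__all__ = ["LikelihoodEvaluator", "forward_loglik", "viterbi_states",
           "stationary_fraction", "forward_from_emissions",
           "enumerate_loglik"]

_TWO_PI = 2.0 * np.pi


def stationary_fraction(lambda_: float, gamma_: float) -> tuple[float, float]:
    """Occupancy split reported as (lambda, gamma) / (lambda + gamma) -
    the conventional summary of time spent stationary vs non-stationary."""
    tot = lambda_ + gamma_
    if tot <= 0:
        raise ValueError("lambda + gamma must be positive")
    return lambda_ / tot, gamma_ / tot


def chain_stationary_distribution(lambda_: float, gamma_: float) -> np.ndarray:
    """Stationary distribution of [[lam, 1-lam], [1-gam, gam]]."""
    denom = 2.0 - lambda_ - gamma_
    if denom <= 0:
        raise ValueError("invalid persistence probabilities")
    return np.array([(1.0 - gamma_) / denom, (1.0 - lambda_) / denom])


# ----------------------------------------------------------------------
# numba kernel: memory bracket over candidates

@njit(cache=True, fastmath=True)
def _memory_bracket_kernel(points, to_fix, pos, defined, dt_h, mu_h, sig_h,
                           inv_scale, beta_d, use_gates, tilde0, path_r,
                           mask, beta, step=1):  # pragma: no cover
    """For each step t and endpoint c, the memory bracket

        (1 - beta_d) + beta_d * sum_l w_l * gate_l * exp(-d_{c,l} * inv_scale)

    with Gaussian lag weights w_l (truncated at 5 sigma, renormalized over
    defined lags).  Steps with no defined lag get bracket 1 (fallback).
    """
    T, C = points.shape[0], points.shape[1]
    out = np.ones((T, C))
    fallback = np.zeros(T, dtype=np.bool_)
    lo = int(np.ceil((mu_h - LAG_TRUNCATION_SD * sig_h) / dt_h - 1e-9))
    if lo < 1:
        lo = 1
    if step > 1:  # align to the strided lag grid (anchored at 0)
        lo = ((lo + step - 1) // step) * step
    hi = int(np.floor((mu_h + LAG_TRUNCATION_SD * sig_h) / dt_h + 1e-9))
    P = beta.shape[0]
    for t in range(T):
        tf = to_fix[t]
        h = hi if hi < tf else tf
        wsum = 0.0
        for l in range(lo, h + 1, step):
            j = tf - l
            if defined[j]:
                tau = l * dt_h
                wsum += np.exp(-0.5 * ((tau - mu_h) / sig_h) ** 2)
        if wsum <= 0.0:
            fallback[t] = True
            continue
        acc = np.zeros(C)
        for l in range(lo, h + 1, step):
            j = tf - l
            if not defined[j]:
                continue
            tau = l * dt_h
            w = np.exp(-0.5 * ((tau - mu_h) / sig_h) ** 2) / wsum
            gate = 1.0
            if use_gates:
                score = tilde0
                for p in range(P):
                    score += path_r[j, p] * mask[t, p] * beta[p]
                gate = 1.0 / (1.0 + np.exp(-score))
            zx, zy = pos[j, 0], pos[j, 1]
            wg = w * gate
            for c in range(C):
                dx = points[t, c, 0] - zx
                dy = points[t, c, 1] - zy
                d2 = dx * dx + dy * dy
                if d2 * inv_scale * inv_scale <= 900.0:
                    acc[c] += wg * np.exp(-np.sqrt(d2) * inv_scale)
        for c in range(C):
            out[t, c] = (1.0 - beta_d) + beta_d * acc[c]
    return out, fallback


@njit(cache=True, fastmath=True)
def _build_decay(points, pos, jc, defined, inv):  # pragma: no cover
    """exp(-distance * inv) from each endpoint to each lagged location.

    Stored in float32: the tensor is only ever summed against smooth
    weights, and the finite-difference perturbations that matter reuse
    the identical cached tensor, so the rounding cancels.
    """
    T, C = points.shape[0], points.shape[1]
    L = jc.shape[1]
    out = np.empty((T, C, L), dtype=np.float32)
    for t in range(T):
        for k in range(L):
            if defined[t, k] == 0.0:
                for c in range(C):
                    out[t, c, k] = 0.0
                continue
            zx = pos[jc[t, k], 0]
            zy = pos[jc[t, k], 1]
            for c in range(C):
                dx = points[t, c, 0] - zx
                dy = points[t, c, 1] - zy
                d2 = dx * dx + dy * dy
                if d2 * inv * inv > 900.0:  # exp(-30) ~ 1e-13: zero
                    out[t, c, k] = 0.0
                else:
                    out[t, c, k] = np.exp(-np.sqrt(d2) * inv)
    return out


# ----------------------------------------------------------------------
# evaluator

class LikelihoodEvaluator:
    """Precomputed per-track state for fast repeated likelihood evaluation.

    Candidate endpoints are re-derived each call from a fixed array of
    uniform variates by inverse-CDF, so the approximated likelihood is a
    smooth function of (rho_ns, kappa) and identical candidate randomness
    is shared across models (common random numbers).

    Parameters
    ----------
    track : Track
    landscape : Landscape or None (required for resource models)
    A : int
        Available steps per observed step (Monte-Carlo normalization).
    seed : int
        Seeds the candidate uniforms.
    """

    def __init__(self, track, landscape=None, A: int = 50, seed: int = 0):
        self.track = track
        self.landscape = landscape
        self.A = int(A)
        self.seed = int(seed)
        if self.A < 1:
            raise ValueError("A must be >= 1")

        steps = track.steps()
        em = steps[~steps["training"].to_numpy()].reset_index(drop=True)
        if len(em) < 1:
            raise ValueError("track has no post-training steps")
        self.steps = em
        self.n_obs = len(em)
        fi = em["from_idx"].to_numpy()
        ti = em["to_idx"].to_numpy()
        self.start = track.xy[fi]
        self.obs = track.xy[ti]
        self.obs_len = em["length"].to_numpy()
        self.obs_turn = np.nan_to_num(em["turn"].to_numpy())
        self.hd = em["heading_defined"].to_numpy()
        self.heading_in = em["heading_in"].to_numpy()
        self.doy = em["doy"].to_numpy()
        self.dt = float(track.dt_hours)
        self.to_fix = track.fix_index[ti]
        # segment starts: forward recursion restarts where steps disconnect
        self.new_segment = np.ones(self.n_obs, dtype=bool)
        self.new_segment[1:] = fi[1:] != ti[:-1]

        rng = np.random.default_rng(self.seed)
        self.uniforms = rng.uniform(size=(self.n_obs, self.A, 2))

        self.pos, self.defined = track.indexed_path()
        self._stat_logs = stationary_log_density(self.obs_len)
        # covariates along the path and at observed endpoints (raw)
        if landscape is not None:
            self.path_r = np.zeros((len(self.pos), landscape.n_layers))
            if self.defined.any():
                self.path_r[self.defined] = landscape.covariates_at(
                    self.pos[self.defined], seasonal=False, clamp=True)
            self.obs_r = landscape.covariates_at(self.obs, seasonal=False,
                                                 clamp=True)
            self.P = landscape.n_layers
        else:
            self.path_r = np.zeros((len(self.pos), 1))
            self.obs_r = None
            self.P = 0
        #: lag-grid stride for the memory sum: 1 = every fix (exact,
        #: default); the staged optimizer coarsens to daily lags and
        #: re-normalizes the Gaussian weights (sigma >= 3 d makes the
        #: daily approximation accurate), polishing and reporting exactly.
        self.lag_stride = 1
        self._mask_cache: dict[bool, np.ndarray] = {}
        self._cand_cache: tuple | None = None
        self._lag_meta_cache: tuple | None = None
        self._decay_cache: tuple | None = None
        self._emission_cache: tuple | None = None
        self.n_out_of_extent = 0

    # -- candidates ----------------------------------------------------
    def candidate_endpoints(self, rho_ns: float, kappa: float) -> np.ndarray:
        """(T, A, 2) endpoints drawn from k via the fixed uniforms."""
        key = (rho_ns, kappa)
        if self._cand_cache is not None and self._cand_cache[0] == key:
            return self._cand_cache[1]
        u = self.uniforms
        lengths = -rho_ns * self.dt * np.log1p(-np.clip(u[..., 0], 0, 1 - 1e-12))
        turn = wrapped_cauchy_ppf(u[..., 1], kappa)
        directions = np.where(self.hd[:, None],
                              np.nan_to_num(self.heading_in)[:, None] + turn,
                              _TWO_PI * (u[..., 1] - 0.5))
        endpoints = self.start[:, None, :] + lengths[..., None] * np.stack(
            [np.cos(directions), np.sin(directions)], axis=-1)
        cand_r = None
        if self.landscape is not None:
            flat = endpoints.reshape(-1, 2)
            inext = self.landscape.in_extent(flat)
            self.n_out_of_extent = int((~inext).sum())
            cand_r = self.landscape.covariates_at(flat, seasonal=False,
                                                  clamp=True).reshape(
                self.n_obs, self.A, self.P)
        self._cand_cache = (key, endpoints, cand_r)
        return endpoints

    def _cand_r(self, rho_ns, kappa):
        self.candidate_endpoints(rho_ns, kappa)
        return self._cand_cache[2]

    def _season_mask(self, seasonal: bool) -> np.ndarray:
        if seasonal not in self._mask_cache:
            if self.landscape is None:
                m = np.ones((self.n_obs, 1))
            elif seasonal:
                m = self.landscape.seasonal_mask(self.doy)
            else:
                m = np.ones((self.n_obs, self.P))
            self._mask_cache[seasonal] = m
        return self._mask_cache[seasonal]

    # -- memory bracket via cached distance/decay tensors --------------
    def _window(self, mu_days: float, sigma_days: float) -> tuple[int, int]:
        """Integer lag-index window [lo, hi] covering the 5-sigma truncation
        of the Gaussian revisitation schedule, expanded outward to whole
        days so that small moves of (mu, sigma) keep the cached decay
        tensor valid (the exact truncation is applied as a weight mask)."""
        mu_h, sig_h = mu_days * 24.0, sigma_days * 24.0
        q = max(1, int(round(24.0 / self.dt)))  # lags per day
        lo = int(np.ceil((mu_h - LAG_TRUNCATION_SD * sig_h) / self.dt - 1e-9))
        hi = int(np.floor((mu_h + LAG_TRUNCATION_SD * sig_h) / self.dt + 1e-9))
        lo = max(1, (lo // q) * q)
        hi = ((hi + q) // q) * q
        hi = min(hi, int(self.to_fix.max()))  # lags beyond the track: undefined
        return lo, max(hi, lo)

    #: cached decay tensors above this element count are not built; the
    #: bracket streams through the numba kernel instead (rare, far-from-
    #: optimum probes with very wide lag windows).
    MAX_CACHED_ELEMENTS = 320_000_000

    def _lag_meta(self, lo: int, hi: int):
        """Strided lag indices, their (T, L) defined mask and (T, L) path
        row lookup for the window [lo, hi] (depends on the track only)."""
        key = (lo, hi, self.lag_stride)
        if self._lag_meta_cache is not None and self._lag_meta_cache[0] == key:
            return self._lag_meta_cache[1:]
        lags = np.arange(lo, hi + 1, self.lag_stride)
        j = self.to_fix[:, None] - lags[None, :]
        ok = j >= 0
        jc = np.clip(j, 0, len(self.pos) - 1)
        defined = (ok & self.defined[jc]).astype(float)
        self._lag_meta_cache = (key, lags, defined, jc)
        return lags, defined, jc

    def _ensure_decay(self, rho_ns: float, kappa: float, lo: int, hi: int,
                      alpha: float):
        """(T, A+1, L) tensor exp(-||endpoint - z_lag|| / 10**alpha), zero
        at undefined lags.  Cached: finite-difference perturbations of mu,
        sigma, beta_d, beta, beta0, lambda, gamma reuse it unchanged."""
        key = (rho_ns, kappa, lo, hi, self.lag_stride, alpha)
        if self._decay_cache is not None and self._decay_cache[0] == key:
            return self._decay_cache[1]
        endpoints = self.candidate_endpoints(rho_ns, kappa)
        points = np.ascontiguousarray(
            np.concatenate([self.obs[:, None, :], endpoints], axis=1))
        _, defined, jc = self._lag_meta(lo, hi)
        decay = _build_decay(points, self.pos, jc, defined,
                             10.0 ** (-alpha))
        self._decay_cache = (key, decay)
        return decay

    def memory_bracket(self, params) -> np.ndarray:
        """(T, A+1) memory bracket (1-beta_d) + beta_d * sum_l w_l gate_l
        decay_l for the observed endpoint (col 0) and the candidates."""
        lo, hi = self._window(params.mu, params.sigma)
        T = self.n_obs
        L = (hi - lo) // self.lag_stride + 1
        if T * (self.A + 1) * L > self.MAX_CACHED_ELEMENTS:
            return self._memory_bracket_streaming(params)
        lags, defined, jc = self._lag_meta(lo, hi)
        decay = self._ensure_decay(params.rho_ns, params.kappa, lo, hi,
                                   params.alpha)
        taus = lags * self.dt
        mu_h, sig_h = params.mu * 24.0, params.sigma * 24.0
        phi = np.exp(-0.5 * ((taus - mu_h) / sig_h) ** 2)
        # exact truncation: the cached window is expanded to whole days
        phi[np.abs(taus - mu_h) > LAG_TRUNCATION_SD * sig_h] = 0.0
        w = phi[None, :] * defined
        wsum = w.sum(axis=1)
        if params.model == "resource_memory":
            mask = self._season_mask(params.seasonal)
            r_lag = self.path_r[jc] * defined[..., None]
            score = params.beta0_tilde + np.einsum(
                "tlp,tp->tl", r_lag, mask * params.beta)
            w = w / (1.0 + np.exp(-np.clip(score, -500, 500)))
        # float32 batched matvec (BLAS) over the full tensor (boolean
        # subsetting would copy it); the ~1e-6 relative rounding is far
        # below the optimizer's finite-difference step
        ok = wsum > 0.0
        prod = np.matmul(decay, w.astype(np.float32)[..., None])[..., 0]
        attraction = prod.astype(float) / np.where(ok, wsum, 1.0)[:, None]
        attraction[~ok] = 0.0
        bracket = (1.0 - params.beta_d) + params.beta_d * attraction
        bracket[~ok] = 1.0  # no defined lags: memory contributes nothing
        return bracket

    def _memory_bracket_streaming(self, params) -> np.ndarray:
        """Same bracket via the constant-memory numba kernel."""
        endpoints = self.candidate_endpoints(params.rho_ns, params.kappa)
        points = np.concatenate([self.obs[:, None, :], endpoints], axis=1)
        use_gates = params.model == "resource_memory"
        mask = self._season_mask(params.seasonal if use_gates else False)
        bracket, _ = _memory_bracket_kernel(
            np.ascontiguousarray(points), self.to_fix, self.pos,
            self.defined, self.dt, params.mu * 24.0, params.sigma * 24.0,
            10.0 ** (-params.alpha), params.beta_d, use_gates,
            params.beta0_tilde if use_gates else 0.0,
            self.path_r, np.ascontiguousarray(mask, dtype=float),
            params.beta, self.lag_stride)
        return bracket

    # -- emissions -----------------------------------------------------
    def emission_logs(self, params) -> np.ndarray:
        """(T, 2) log emission densities: column 0 stationary, 1 moving."""
        logk = crw_log_density(self.obs_len, self.obs_turn, params.rho_ns,
                               params.kappa, self.dt, self.hd)
        if params.model == "null":
            log_fns = logk
        else:
            logW = np.zeros((self.n_obs, self.A + 1))
            if params.uses_resources():
                mask = self._season_mask(params.seasonal)
                r_all = np.concatenate(
                    [self.obs_r[:, None, :],
                     self._cand_r(params.rho_ns, params.kappa)], axis=1)
                logW += np.einsum("tcp,tp,p->tc", r_all, mask, params.beta)
            if params.uses_memory():
                logW += np.log(self.memory_bracket(params))
            norm = _logmeanexp(logW[:, 1:], axis=1)
            if not np.all(np.isfinite(norm)):
                raise DegenerateWeightsError(
                    "all candidate weights vanished for at least one step")
            log_fns = logk + logW[:, 0] - norm
        return np.column_stack([self._stat_logs, log_fns])

    def loglik(self, params) -> float:
        # emission densities do not involve lambda/gamma: cache them so
        # transition-parameter perturbations only rerun the forward pass
        key = (params.model, params.seasonal, params.rho_ns, params.kappa,
               params.alpha, params.mu, params.sigma, params.beta_d,
               params.beta0, params.beta.tobytes())
        if self._emission_cache is not None and self._emission_cache[0] == key:
            em = self._emission_cache[1]
        else:
            em = self.emission_logs(params)
            self._emission_cache = (key, em)
        return forward_from_emissions(em, self.new_segment,
                                      params.lambda_, params.gamma_)

    def viterbi(self, params) -> np.ndarray:
        em = self.emission_logs(params)
        return _viterbi(em, self.new_segment, params.lambda_, params.gamma_)


def _logmeanexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    with np.errstate(over="ignore"):
        out = m.squeeze(axis) + np.log(
            np.mean(np.exp(x - m), axis=axis))
    return out


# ----------------------------------------------------------------------
# forward / viterbi on log emissions

def forward_from_emissions(log_em: np.ndarray, new_segment: np.ndarray,
                           lambda_: float, gamma_: float) -> float:
    """Scaled forward recursion; restarts from the chain's stationary
    distribution at every segment start.  Returns the log-likelihood."""
    P = np.array([[lambda_, 1.0 - lambda_],
                  [1.0 - gamma_, gamma_]])
    init = chain_stationary_distribution(lambda_, gamma_)
    with np.errstate(over="ignore"):
        em = np.exp(log_em - np.max(log_em, axis=1, keepdims=True))
    shift = np.max(log_em, axis=1)
    if not np.all(np.isfinite(shift)):
        return -np.inf
    ll = 0.0
    alpha = None
    for t in range(len(em)):
        alpha = init * em[t] if new_segment[t] else (alpha @ P) * em[t]
        c = alpha.sum()
        if c <= 0 or not np.isfinite(c):
            return -np.inf
        alpha = alpha / c
        ll += np.log(c) + shift[t]
    return float(ll)


def _viterbi(log_em: np.ndarray, new_segment: np.ndarray,
             lambda_: float, gamma_: float) -> np.ndarray:
    logP = np.log(np.array([[lambda_, 1.0 - lambda_],
                            [1.0 - gamma_, gamma_]]))
    log_init = np.log(chain_stationary_distribution(lambda_, gamma_))
    T = len(log_em)
    delta = np.zeros((T, 2))
    argp = np.zeros((T, 2), dtype=np.int64)
    for t in range(T):
        if new_segment[t]:
            delta[t] = log_init + log_em[t]
            argp[t] = -1
        else:
            cand = delta[t - 1][:, None] + logP
            # ties broken toward the stationary state (index 0)
            argp[t] = np.argmax(cand, axis=0)
            delta[t] = cand[argp[t], [0, 1]] + log_em[t]
    states = np.zeros(T, dtype=np.int64)
    states[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        nxt = argp[t + 1, states[t + 1]]
        states[t] = int(np.argmax(delta[t])) if nxt < 0 else int(nxt)
    return states


# ----------------------------------------------------------------------
# module-level wrappers and oracles

def forward_loglik(track, landscape, params, A: int = 50, seed: int = 0,
                   evaluator: LikelihoodEvaluator | None = None) -> float:
    """Exact two-state forward log-likelihood of a track (nats)."""
    if evaluator is None:
        evaluator = LikelihoodEvaluator(track, landscape, A=A, seed=seed)
    return evaluator.loglik(params)


def viterbi_states(track, landscape, params, A: int = 50, seed: int = 0,
                   evaluator: LikelihoodEvaluator | None = None) -> np.ndarray:
    """Most probable state path (0 = stationary, 1 = non-stationary)."""
    if evaluator is None:
        evaluator = LikelihoodEvaluator(track, landscape, A=A, seed=seed)
    return evaluator.viterbi(params)


def enumerate_loglik(log_em: np.ndarray, new_segment: np.ndarray,
                     lambda_: float, gamma_: float) -> float:
    """Brute-force log-likelihood summing over all 2^T state sequences.

    Independent oracle for :func:`forward_from_emissions`; only feasible
    for very short tracks.
    """
    from itertools import product

    P = np.array([[lambda_, 1.0 - lambda_], [1.0 - gamma_, gamma_]])
    init = chain_stationary_distribution(lambda_, gamma_)
    T = len(log_em)
    total = 0.0
    for path in product((0, 1), repeat=T):
        lp = 0.0
        for t, s in enumerate(path):
            if new_segment[t]:
                lp += np.log(init[s]) + log_em[t, s]
            else:
                lp += np.log(P[path[t - 1], s]) + log_em[t, s]
        total += np.exp(lp)
    return float(np.log(total))
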