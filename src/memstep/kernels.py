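"""Movement kernels and step-selection weighting functions.

The non-stationary step density is a normalized product

    f_ns(x_t | x_{t-1}, phi_{t-1}, Z_{t-1})
        = k(x_t | x_{t-1}, phi_{t-1}) W(x_t | Z_{t-1}) / integral(k W),

where ``k`` is a correlated-random-walk kernel (exponential step lengths
with mean rho_ns * dt; wrapped-Cauchy turning angles with concentration
kappa) and ``W`` is one of four weighting functions:

- W_N = 1 (null; f_ns reduces to k);
- W_R = exp(sum_p beta_p r_p(x)) (resource selection);
- W_M = (1 - beta_d) + beta_d * attraction (memory), where *attraction* is
  a Gaussian-lag-weighted average of exp(-distance / 10**alpha) to the
  locations occupied mu +/- sigma days ago;
- W_RM = W_R * [(1 - beta_d) + beta_d * sum_tau w_tau * gate_tau *
  exp(-d_tau / 10**alpha)], where the logistic *gate* downweights
  revisitation of remembered locations with poor resources.

The normalizing integral is approximated by Monte Carlo: "available"
endpoints are drawn from ``k`` itself, so the sample mean of W over the
candidates estimates integral(k W).

Densities are planar (per km^2): the polar-coordinate Jacobian 1/length is
applied here and in the stationary emission, nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cognitive import CognitiveMap
from .errors import DegenerateWeightsError, UndefinedMemoryError

__all__ = [
    "STATIONARY_MEAN_KM", "STATIONARY_SCALE_KM", "LAG_TRUNCATION_SD",
    "wrapped_cauchy_pdf", "wrapped_cauchy_ppf", "crw_density",
    "crw_log_density", "stationary_density", "stationary_log_density",
    "sample_stationary_length",
    "w_null", "w_resource", "memory_attraction", "w_memory",
    "revisit_gate", "w_resource_memory",
    "CandidateSet", "draw_candidates", "f_ns_hat",
]

#: Mean stationary-state step length, km (fixed at the raster cell size).
STATIONARY_MEAN_KM = 0.03
#: Half-normal scale giving that mean: mean = scale * sqrt(2/pi).
STATIONARY_SCALE_KM = STATIONARY_MEAN_KM * np.sqrt(np.pi / 2.0)
#: Gaussian lag weights are truncated at |tau - mu| > 5 sigma.
LAG_TRUNCATION_SD = 5.0

_TWO_PI = 2.0 * np.pi


# ----------------------------------------------------------------------
# resource-independent kernel k

def wrapped_cauchy_pdf(theta, kappa: float):
    """Wrapped-Cauchy density on (-pi, pi], centre 0, concentration kappa."""
    if not (0 <= kappa < 1):
        raise ValueError(f"kappa must lie in [0, 1), got {kappa}")
    theta = np.asarray(theta, dtype=float)
    return (1 - kappa ** 2) / (_TWO_PI * (1 + kappa ** 2
                                          - 2 * kappa * np.cos(theta)))


def wrapped_cauchy_ppf(u, kappa: float):
    """Inverse CDF: maps Uniform(0,1) draws to turning angles.

    Used for common-random-number candidate sampling: the same uniforms
    yield angles that vary smoothly with kappa.
    """
    if not (0 <= kappa < 1):
        raise ValueError(f"kappa must lie in [0, 1), got {kappa}")
    u = np.asarray(u, dtype=float)
    return 2.0 * np.arctan((1 - kappa) / (1 + kappa)
                           * np.tan(np.pi * (u - 0.5)))


def crw_log_density(length, turn, rho_ns: float, kappa: float,
                    dt_hours: float, heading_defined=True):
    """log k: planar density of a step of given length (km) and turning
    angle (radians) in the non-stationary state.

    Exponential lengths with mean rho_ns * dt; wrapped-Cauchy angles (or
    uniform 1/(2 pi) where the inbound heading is undefined, e.g. the
    first step of a burst); divided by length for the polar Jacobian.
    """
    length = np.asarray(length, dtype=float)
    mean_len = rho_ns * dt_hours
    if mean_len <= 0:
        raise ValueError("rho_ns and dt must be positive")
    log_len = -length / mean_len - np.log(mean_len)
    hd = np.asarray(heading_defined, dtype=bool)
    ang = np.where(hd,
                   wrapped_cauchy_pdf(np.where(hd, turn, 0.0), kappa),
                   1.0 / _TWO_PI)
    return log_len + np.log(ang) - np.log(np.maximum(length, 1e-12))


def crw_density(length, turn, rho_ns: float, kappa: float, dt_hours: float,
                heading_defined=True):
    return np.exp(crw_log_density(length, turn, rho_ns, kappa, dt_hours,
                                  heading_defined))


def stationary_log_density(length):
    """log planar density of a stationary-state step: half-normal length
    (mean fixed at 30 m) times a uniform angle, with the polar Jacobian."""
    length = np.asarray(length, dtype=float)
    s = STATIONARY_SCALE_KM
    with np.errstate(divide="ignore"):
        out = np.where(
            length >= 0,
            np.log(2.0) - 0.5 * np.log(_TWO_PI * s * s)
            - 0.5 * (length / s) ** 2
            - np.log(_TWO_PI) - np.log(np.maximum(length, 1e-12)),
            -np.inf,
        )
    return out


def stationary_density(length):
    """Half-normal step-length density (per km, angle integrated out)."""
    length = np.asarray(length, dtype=float)
    s = STATIONARY_SCALE_KM
    return np.where(length >= 0,
                    np.sqrt(2.0 / np.pi) / s * np.exp(-0.5 * (length / s) ** 2),
                    0.0)


def sample_stationary_length(rng: np.random.Generator, size=None):
    return np.abs(rng.normal(0.0, STATIONARY_SCALE_KM, size=size))


# ----------------------------------------------------------------------
# weighting functions

def w_null(point=None) -> float:
    """W_N = 1 everywhere (f_ns reduces to k)."""
    return 1.0


def w_resource(r, beta):
    """W_R = exp(sum_p beta_p r_p)."""
    r = np.asarray(r, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if r.shape[-1] != beta.shape[-1]:
        raise ValueError(f"covariate/coefficient length mismatch: "
                         f"{r.shape[-1]} vs {beta.shape[-1]}")
    return np.exp(r @ beta)


def _lag_weights(t: float, cmap: CognitiveMap, mu_days: float,
                 sigma_days: float, dt_fix_hours: float):
    """Defined lags (hours), their remembered locations and normalized
    Gaussian weights, truncated at |tau - mu| > 5 sigma."""
    mu_h = mu_days * 24.0
    sig_h = sigma_days * 24.0
    lo = max(dt_fix_hours, mu_h - LAG_TRUNCATION_SD * sig_h)
    hi = mu_h + LAG_TRUNCATION_SD * sig_h
    if cmap.t_start is not None:
        hi = min(hi, t - cmap.t_start)
    taus, locs = [], []
    k = int(np.ceil(lo / dt_fix_hours - 1e-9))
    tau = k * dt_fix_hours
    while tau <= hi + 1e-9:
        z = cmap.location_at_lag(t, tau)
        if z is not None:
            taus.append(tau)
            locs.append(z)
        tau += dt_fix_hours
    if not taus:
        raise UndefinedMemoryError(
            f"no defined lags at t={t} for mu={mu_days} d, sigma={sigma_days} d"
        )
    taus = np.asarray(taus)
    w = np.exp(-0.5 * ((taus - mu_h) / sig_h) ** 2)
    return taus, np.asarray(locs), w / w.sum()


def memory_attraction(point, t: float, cmap: CognitiveMap, mu_days: float,
                      sigma_days: float, alpha: float,
                      dt_fix_hours: float = 4.0) -> float:
    """Gaussian-lag-weighted average of exp(-distance / 10**alpha) from
    ``point`` to the locations occupied ~mu days ago.  Lies in [0, 1]."""
    _, locs, w = _lag_weights(t, cmap, mu_days, sigma_days, dt_fix_hours)
    d = np.hypot(*(np.asarray(point, dtype=float) - locs).T)
    return float(w @ np.exp(-d / 10.0 ** alpha))


def w_memory(attraction: float, beta_d: float) -> float:
    """W_M = (1 - beta_d) + beta_d * attraction, in (1 - beta_d, 1]."""
    return (1.0 - beta_d) + beta_d * attraction


def revisit_gate(r_at_memory, beta, beta0: float):
    """logistic(logit(beta0) + beta . r(z)): probability that a remembered
    location is attractive for revisitation given its resources.  Equals
    beta0 exactly when the remembered covariates are all zero."""
    r = np.asarray(r_at_memory, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if r.shape[-1] != beta.shape[-1]:
        raise ValueError("covariate/coefficient length mismatch")
    tilde0 = np.log(beta0 / (1.0 - beta0))
    return expit(tilde0 + r @ beta)


def w_resource_memory(point, t: float, cmap: CognitiveMap, landscape,
                      params, doy: int | None = None,
                      dt_fix_hours: float = 4.0) -> float:
    """W_RM = W_R(x) * [(1 - beta_d) + beta_d * sum_tau w_tau *
    gate(r(z_{t-tau})) * exp(-||x - z_{t-tau}|| / 10**alpha)].

    Falls back to the pure resource weight when no lags are defined.
    """
    seasonal = params.seasonal
    r_here = landscape.covariates_at(point, doy=doy, seasonal=seasonal,
                                     clamp=True)
    wr = float(w_resource(r_here, params.beta))
    try:
        _, locs, w = _lag_weights(t, cmap, params.mu, params.sigma,
                                  dt_fix_hours)
    except UndefinedMemoryError:
        return wr
    r_mem = landscape.covariates_at(locs, doy=doy, seasonal=seasonal,
                                    clamp=True)
    gates = revisit_gate(r_mem, params.beta, params.beta0)
    d = np.hypot(*(np.asarray(point, dtype=float) - locs).T)
    bracket = (1.0 - params.beta_d) \
        + params.beta_d * float(w @ (gates * np.exp(-d / 10.0 ** params.alpha)))
    return wr * bracket


# ----------------------------------------------------------------------
# Monte-Carlo normalization

@dataclass
class CandidateSet:
    """Observed step plus A alternative endpoints sampled from k."""

    start: np.ndarray          # (2,) from-location
    heading_in: float          # radians; NaN if undefined
    dt_hours: float
    observed: np.ndarray       # (2,) observed endpoint
    endpoints: np.ndarray      # (A, 2) candidate endpoints
    rng_stream_id: int = 0


def draw_candidates(uniforms: np.ndarray, start, heading_in: float,
                    rho_ns: float, kappa: float, dt_hours: float,
                    observed=None, rng_stream_id: int = 0) -> CandidateSet:
    """Draw A endpoints from k by inverse-CDF from given Uniform(0,1)
    pairs, so the same uniforms give candidates that move smoothly with
    (rho_ns, kappa).

    ``uniforms`` is (A, 2): column 0 -> step length, column 1 -> angle.
    With an undefined inbound heading the absolute direction is uniform.
    """
    u = np.asarray(uniforms, dtype=float)
    start = np.asarray(start, dtype=float)
    lengths = -rho_ns * dt_hours * np.log1p(-np.clip(u[:, 0], 0, 1 - 1e-12))
    if np.isnan(heading_in):
        directions = _TWO_PI * (u[:, 1] - 0.5)
    else:
        directions = heading_in + wrapped_cauchy_ppf(u[:, 1], kappa)
    endpoints = start + lengths[:, None] * np.column_stack(
        [np.cos(directions), np.sin(directions)])
    return CandidateSet(start=start, heading_in=heading_in, dt_hours=dt_hours,
                        observed=None if observed is None
                        else np.asarray(observed, dtype=float),
                        endpoints=endpoints, rng_stream_id=rng_stream_id)


def f_ns_hat(candidate_set: CandidateSet, params, weight_fn) -> float:
    """Monte-Carlo estimate of the normalized step density:

        k(observed) * W(observed) / mean_a W(candidate_a).

    Candidates must have been drawn from k with the same (rho_ns, kappa).
    ``weight_fn`` maps an endpoint to its W value.
    """
    cs = candidate_set
    if cs.observed is None:
        raise ValueError("candidate set lacks an observed endpoint")
    d = cs.observed - cs.start
    length = float(np.hypot(*d))
    direction = float(np.arctan2(d[1], d[0]))
    hd = not np.isnan(cs.heading_in)
    turn = direction - cs.heading_in if hd else 0.0
    k_obs = float(crw_density(length, turn, params.rho_ns, params.kappa,
                              cs.dt_hours, heading_defined=hd))
    w_obs = float(weight_fn(cs.observed))
    w_cand = np.asarray([weight_fn(e) for e in cs.endpoints], dtype=float)
    denom = float(w_cand.mean())
    if denom <= 0.0:
        raise DegenerateWeightsError("all candidate weights are zero")
    return k_obs * w_obs / denom
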