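"""Model parameters, per-model active subsets, and optimizer transforms.

The four nested movement hypotheses share one parameter vector:

========  ==========  =====================================================
name      units       meaning
========  ==========  =====================================================
rho_ns    km/h        mean movement speed in the non-stationary state
kappa     --          directional autocorrelation (wrapped-Cauchy rho)
beta0     --          probability of revisitation ("threshold" gate level)
beta_1..6 -- or 1/km  resource selection coefficients
beta_d    --          strength of selection for memorized areas
mu        days        mean time lag between revisitations
sigma     days        sd of the revisitation lag (lower bound 3 days)
alpha     log10(km)   perceptual-resolution decay scale (10**alpha km)
lambda_   --          P(stay stationary)
gamma_    --          P(stay non-stationary)
========  ==========  =====================================================

Free subsets: null {rho, kappa, lambda, gamma}; resource adds beta_1..P;
memory adds {beta_d, mu, sigma, alpha} (beta0 fixed at expit(1));
resource-memory adds beta0 on top of everything.

Optimization runs on an unconstrained transformed scale: log for rho_ns;
logit for kappa, beta0, beta_d, lambda, gamma; shifted log for sigma
(sigma = SIGMA_MIN + exp(s)); scaled logit for mu on [MU_MIN, MU_MAX];
identity for the betas and alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

__all__ = ["ParamSet", "MODELS", "active_names", "n_free_params",
           "SIGMA_MIN", "MU_MIN", "MU_MAX", "BETA0_FIXED_MEMORY"]

MODELS = ("null", "resource", "memory", "resource_memory")

SIGMA_MIN = 3.0     # days; optimization lower bound for sigma
SIGMA_MAX = 45.0    # days; upper optimization bound (reported fits top out ~42)
MU_MIN = 3.0        # days
MU_MAX = 400.0      # days; admits circannual (~365 d) revisitation
#: beta0 held fixed (not estimated) in the memory-only model: expit(1).
BETA0_FIXED_MEMORY = float(expit(1.0))

_MEMORY = ["beta_d", "mu", "sigma", "alpha"]


def _beta_names(P: int) -> list[str]:
    return [f"beta_{p}" for p in range(1, P + 1)]


def active_names(model: str, P: int = 6) -> list[str]:
    """Free-parameter names for a model, in optimizer order.

    The order puts parameters whose finite-difference perturbation is
    cheapest first (lambda, gamma touch only the forward recursion) and
    the kernel parameters (rho_ns, kappa), which force a candidate
    redraw, last - the likelihood evaluator's caches exploit this.
    """
    head = ["lambda_", "gamma_"]
    tail = ["rho_ns", "kappa"]
    if model == "null":
        return head + tail
    if model == "resource":
        return head + _beta_names(P) + tail
    if model == "memory":
        return head + _MEMORY + tail
    if model == "resource_memory":
        return head + _beta_names(P) + ["beta0"] + _MEMORY + tail
    raise ValueError(f"unknown model {model!r}")


def n_free_params(model: str, P: int = 6) -> int:
    return len(active_names(model, P))


@dataclass
class ParamSet:
    """One point in parameter space, plus model/seasonal labels."""

    rho_ns: float = 0.4
    kappa: float = 0.3
    beta: np.ndarray = field(default_factory=lambda: np.zeros(6))
    beta0: float = 0.5
    beta_d: float = 0.5
    mu: float = 100.0
    sigma: float = 10.0
    alpha: float = 0.0
    lambda_: float = 0.4
    gamma_: float = 0.75
    model: str = "null"
    seasonal: bool = False

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (0 <= self.kappa < 1):
            raise ValueError("kappa must lie in [0, 1)")
        if self.rho_ns <= 0:
            raise ValueError("rho_ns must be positive")
        for nm in ("beta0", "beta_d", "lambda_", "gamma_"):
            v = getattr(self, nm)
            if not (0 < v < 1):
                raise ValueError(f"{nm} must lie in (0, 1), got {v}")
        if self.model == "memory":
            self.beta0 = BETA0_FIXED_MEMORY

    @property
    def P(self) -> int:
        return len(self.beta)

    @property
    def beta_d_tilde(self) -> float:
        return float(logit(self.beta_d))

    @property
    def beta0_tilde(self) -> float:
        return float(logit(self.beta0))

    def get(self, name: str) -> float:
        if name.startswith("beta_") and name[5:].isdigit():
            return float(self.beta[int(name[5:]) - 1])
        return float(getattr(self, name))

    def set(self, name: str, value: float) -> None:
        if name.startswith("beta_") and name[5:].isdigit():
            self.beta[int(name[5:]) - 1] = value
        else:
            setattr(self, name, value)

    def copy(self) -> "ParamSet":
        out = replace(self)
        out.beta = self.beta.copy()
        return out

    def uses_resources(self) -> bool:
        return self.model in ("resource", "resource_memory")

    def uses_memory(self) -> bool:
        return self.model in ("memory", "resource_memory")

    # -- transformed (unconstrained) coordinates ----------------------
    def to_vector(self) -> np.ndarray:
        """Free parameters on the unconstrained optimizer scale."""
        return np.array([_to_unc(n, self.get(n)) for n in self.free_names()])

    def free_names(self) -> list[str]:
        return active_names(self.model, self.P)

    def with_vector(self, vec: np.ndarray) -> "ParamSet":
        out = self.copy()
        for name, v in zip(self.free_names(), np.asarray(vec, dtype=float)):
            out.set(name, _from_unc(name, float(v)))
        return out

    def as_dict(self) -> dict:
        d = {"rho_ns": self.rho_ns, "kappa": self.kappa, "beta0": self.beta0,
             "beta_d": self.beta_d, "mu": self.mu, "sigma": self.sigma,
             "alpha": self.alpha, "lambda_": self.lambda_, "gamma_": self.gamma_,
             "model": self.model, "seasonal": self.seasonal}
        for p in range(self.P):
            d[f"beta_{p + 1}"] = float(self.beta[p])
        return d


_CLIP = 1e-9

#: Box bounds on the transformed (unconstrained-scale) coordinates, keeping
#: the optimizer inside numerically sane territory (e.g. sigma <= ~400 d).
_LOGIT_BOUND = 12.0


def unc_bounds(name: str) -> tuple[float, float]:
    if name == "rho_ns":
        return (np.log(1e-3), np.log(20.0))
    if name in ("kappa", "beta0", "beta_d", "lambda_", "gamma_", "mu"):
        return (-_LOGIT_BOUND, _LOGIT_BOUND)
    if name == "sigma":
        return (np.log(0.1), np.log(SIGMA_MAX - SIGMA_MIN))
    if name == "alpha":
        return (-4.0, 3.0)
    return (-30.0, 30.0)  # betas


def _to_unc(name: str, value: float) -> float:
    if name == "rho_ns":
        return np.log(value)
    if name in ("kappa", "beta0", "beta_d", "lambda_", "gamma_"):
        return float(logit(np.clip(value, _CLIP, 1 - _CLIP)))
    if name == "sigma":
        return np.log(max(value - SIGMA_MIN, _CLIP))
    if name == "mu":
        frac = (value - MU_MIN) / (MU_MAX - MU_MIN)
        return float(logit(np.clip(frac, _CLIP, 1 - _CLIP)))
    return float(value)  # betas, alpha


def _from_unc(name: str, v: float) -> float:
    if name == "rho_ns":
        return float(np.exp(np.clip(v, -30, 30)))
    if name in ("kappa", "beta0", "beta_d", "lambda_", "gamma_"):
        return float(np.clip(expit(v), _CLIP, 1 - _CLIP))
    if name == "sigma":
        return SIGMA_MIN + float(np.exp(np.clip(v, -30, 30)))
    if name == "mu":
        return MU_MIN + (MU_MAX - MU_MIN) * float(expit(v))
    return float(v)
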