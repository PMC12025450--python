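"""Synthetic cohort generators for the simulation designs.

Two generative frameworks:

* **Binary** — outcome Y ~ Bernoulli(event rate), covariates drawn from the
  class-conditional multivariate normals X|Y=0 ~ N(mu0, Sigma) and
  X|Y=1 ~ N(mu1, Sigma).  With Sigma = I and mu1 - mu0 = delta, the marginal
  AUC of the single covariate x_j is Phi(|delta_j| / sqrt(2)).

* **Survival** — proportional-hazards Weibull failure times with survival
  S(t|x) = exp(-(t/scale)^shape * exp(beta'x)), five independent N(0,1)
  covariates, and either administrative (type I, at the follow-up horizon)
  or uniform random censoring.  The baseline scale is calibrated so the
  marginal probability of failure by the horizon hits a target incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, special

__all__ = [
    "BinaryDesign",
    "SurvivalDesign",
    "CohortData",
    "InvalidDesignError",
    "generate_binary_cohort",
    "calibrate_weibull_scale",
    "generate_survival_cohort",
]

#: effect sizes (components of mu1) used throughout the binary simulations
DEFAULT_MU1 = (0.7, 0.0, 0.2, 0.5, 0.8)
#: hazard ratios used throughout the survival simulations
DEFAULT_HAZARD_RATIOS = (2.0, 1.0, 1.2, 1.5, 2.0)


class InvalidDesignError(ValueError):
    """A design violates its invariants (e.g. non-PD covariance)."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BinaryDesign:
    """Class-conditional multivariate-normal design for a binary outcome."""

    event_rate: float
    n: int
    mu0: tuple = (0.0,) * 5
    mu1: tuple = DEFAULT_MU1
    sigma: Optional[np.ndarray] = None  # None -> identity

    def __post_init__(self):
        if not 0.0 < self.event_rate < 1.0:
            raise InvalidDesignError("event_rate must lie strictly in (0, 1)")
        if self.n < 1:
            raise InvalidDesignError("n must be positive")
        p = len(self.mu0)
        if len(self.mu1) != p:
            raise InvalidDesignError("mu0 and mu1 dimensions disagree")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != (p, p):
                raise InvalidDesignError("sigma shape does not match mu")
            if not np.allclose(s, s.T):
                raise InvalidDesignError("sigma must be symmetric")
            try:
                np.linalg.cholesky(s)
            except np.linalg.LinAlgError as exc:
                raise InvalidDesignError("sigma is not positive definite") from exc

    @property
    def n_covariates(self) -> int:
        return len(self.mu0)


@dataclass(frozen=True)
class SurvivalDesign:
    """Proportional-hazards Weibull design with right censoring.

    Times are in years.  ``scale`` may be left unset and filled in by
    :func:`calibrate_weibull_scale`.
    """

    incidence_rate: float
    n: int
    shape: float = 2.0
    scale: Optional[float] = None
    followup: float = 10.0
    log_hazard_ratios: tuple = field(
        default_factory=lambda: tuple(np.log(DEFAULT_HAZARD_RATIOS))
    )
    censoring: str = "type1"
    random_censoring_max: Optional[float] = None  # None -> 2 * followup

    def __post_init__(self):
        if not 0.0 < self.incidence_rate < 1.0:
            raise InvalidDesignError("incidence_rate must lie strictly in (0, 1)")
        if self.shape <= 0 or self.followup <= 0:
            raise InvalidDesignError("shape and followup must be positive")
        if self.scale is not None and self.scale <= 0:
            raise InvalidDesignError("scale must be positive")
        if self.censoring not in ("type1", "random"):
            raise InvalidDesignError("censoring must be 'type1' or 'random'")
        if self.n < 1:
            raise InvalidDesignError("n must be positive")

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(np.asarray(self.log_hazard_ratios, dtype=float))

    @property
    def n_covariates(self) -> int:
        return len(self.log_hazard_ratios)

    @property
    def censoring_max(self) -> float:
        if self.random_censoring_max is None:
            return 2.0 * self.followup
        return self.random_censoring_max


@dataclass
class CohortData:
    """Per-subject outcomes and covariates.

    ``time`` and ``true_event_time`` are present only for survival cohorts;
    the latent failure time is retained so oracle checks can see through the
    censoring mechanism.
    """

    y: np.ndarray
    x: np.ndarray
    time: Optional[np.ndarray] = None
    true_event_time: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def is_survival(self) -> bool:
        return self.time is not None

    def subset(self, idx: np.ndarray) -> "CohortData":
        """Row-subset (used by the bootstrap engine)."""
        return CohortData(
            y=self.y[idx],
            x=self.x[idx],
            time=None if self.time is None else self.time[idx],
            true_event_time=(
                None if self.true_event_time is None else self.true_event_time[idx]
            ),
        )


# ---------------------------------------------------------------------------
# binary framework
# ---------------------------------------------------------------------------

def generate_binary_cohort(design: BinaryDesign, seed) -> CohortData:
    """Draw a binary-outcome cohort from the class-conditional MVN design.

    Event status is Bernoulli(event_rate) per subject (the event count is
    random, not a fixed quota), then covariates are drawn from the normal of
    the subject's class.  Deterministic given (design, seed).
    """
    rng = _as_rng(seed)
    p = design.n_covariates
    y = (rng.random(design.n) < design.event_rate).astype(np.int8)
    z = rng.standard_normal((design.n, p))
    if design.sigma is not None:
        z = z @ np.linalg.cholesky(np.asarray(design.sigma, dtype=float)).T
    mu = np.where(y[:, None] == 1, np.asarray(design.mu1), np.asarray(design.mu0))
    return CohortData(y=y, x=mu + z)


# ---------------------------------------------------------------------------
# survival framework
# ---------------------------------------------------------------------------

def _marginal_incidence(scale: float, shape: float, tau: float, sd_lp: float) -> float:
    """P(U <= tau) averaged over x for the PH-Weibull model.

    The linear predictor beta'x with x ~ N(0, I) is N(0, sd_lp^2), so the
    marginal incidence is a 1-D Gaussian integral, evaluated by Gauss-Hermite
    quadrature:  E_g[1 - exp(-(tau/scale)^shape * e^g)].
    """
    base = (tau / scale) ** shape
    if sd_lp == 0.0:
        return -np.expm1(-base)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    g = nodes * sd_lp
    vals = -np.expm1(-base * np.exp(g))
    return float(np.sum(weights * vals) / np.sqrt(2.0 * np.pi))


def calibrate_weibull_scale(design: SurvivalDesign, precision: float = 1e-8) -> float:
    """Solve for the baseline Weibull scale hitting the target incidence.

    Closed form when all hazard ratios are 1:
    ``scale = tau / (-log(1 - incidence))**(1/shape)``.  Otherwise the
    marginal incidence (a monotone decreasing function of the scale) is
    inverted by Brent's method on the Gauss-Hermite quadrature estimate.
    """
    target = design.incidence_rate
    tau = design.followup
    beta = np.asarray(design.log_hazard_ratios, dtype=float)
    sd_lp = float(np.linalg.norm(beta))
    if sd_lp == 0.0:
        return tau / (-np.log1p(-target)) ** (1.0 / design.shape)

    def f(log_scale):
        return _marginal_incidence(np.exp(log_scale), design.shape, tau, sd_lp) - target

    # bracket on the log scale; incidence is monotone decreasing in scale
    lo, hi = np.log(tau) - 12.0, np.log(tau) + 12.0
    sol = optimize.brentq(f, lo, hi, xtol=precision)
    return float(np.exp(sol))


def generate_survival_cohort(design: SurvivalDesign, seed) -> CohortData:
    """Draw a right-censored survival cohort from the PH-Weibull design.

    Latent failure times come from inverting the conditional survival
    function: ``U = scale * (-log(u) / exp(beta'x))**(1/shape)`` with
    u ~ Uniform(0,1).  Type I censoring truncates at the follow-up horizon;
    random censoring draws C ~ Uniform(0, random_censoring_max) and then
    also truncates administratively at the horizon.  Censoring is
    independent of U and x (non-informative).
    """
    if design.scale is None:
        design = replace(design, scale=calibrate_weibull_scale(design))
    rng = _as_rng(seed)
    p = design.n_covariates
    x = rng.standard_normal((design.n, p))
    lp = x @ np.asarray(design.log_hazard_ratios, dtype=float)
    u = rng.random(design.n)
    latent = design.scale * (-np.log(u) / np.exp(lp)) ** (1.0 / design.shape)
    if design.censoring == "type1":
        cens = np.full(design.n, design.followup)
    else:
        cens = np.minimum(rng.uniform(0.0, design.censoring_max, design.n),
                          design.followup)
    time = np.minimum(latent, cens)
    y = (latent <= cens).astype(np.int8)
    return CohortData(y=y, x=x, time=time, true_event_time=latent)
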