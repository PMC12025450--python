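"""Nested risk-model fitting and per-subject predicted event probabilities.

The standard model uses the established predictor x1 alone; each expanded
model adds one candidate marker.  Binary outcomes are fit by maximum
likelihood logistic regression (Newton/IRLS); survival outcomes by Cox
proportional-hazards partial likelihood with Breslow tie handling and the
Breslow baseline cumulative-hazard estimator.

The fitters are implemented directly on numpy: the bootstrap coverage
study refits both nested models on every resample (hundreds of thousands
of fits per run), so the hot path is a dedicated small-p Newton solver.
Correctness is pinned against general-purpose reference implementations
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for CLI)

from .synthetic_data import CohortData

__all__ = [
    "FittedModel",
    "RiskPairs",
    "FitError",
    "SeparationError",
    "fit_logistic",
    "fit_cox",
    "predict_event_probability",
    "build_risk_pairs",
]

GRADIENT_TOL = 1e-8  # scaled by n: the score is a sum of n bounded terms
MAX_ITER = 100


class FitError(RuntimeError):
    """Model fitting failed (non-convergence, degenerate outcome, ...)."""


class SeparationError(FitError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class FittedModel:
    kind: str  # "logistic" | "cox"
    covariate_indices: tuple
    coefficients: np.ndarray
    intercept: Optional[float] = None  # logistic only
    baseline_survival_at_tau: Optional[float] = None  # cox only
    horizon: Optional[float] = None  # cox only
    n_iter: int = 0
    gradient_norm: float = np.nan

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return x[:, list(self.covariate_indices)] @ self.coefficients


@dataclass
class RiskPairs:
    """Aligned per-subject paired predictions from the nested models.

    Stored column-wise (struct of arrays); subject order matches the cohort.
    """

    y: np.ndarray
    p_old: np.ndarray
    p_new: np.ndarray
    z_old: np.ndarray
    z_new: np.ndarray
    time: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(
    cohort: CohortData,
    covariate_indices: Sequence[int],
    start: Optional[np.ndarray] = None,
) -> FittedModel:
    """Maximum-likelihood logistic fit of y on the selected covariates.

    Newton-Raphson on the log likelihood; the intercept score equation
    forces the mean fitted probability to equal the observed event rate.
    ``start`` (intercept followed by slopes) warm-starts the iteration —
    the bootstrap engine passes the original-sample fit, which roughly
    halves the iteration count on resamples without changing the optimum.
    """
    y = np.asarray(cohort.y, dtype=float)
    if cohort.n < 10:
        raise FitError("need at least 10 subjects")
    if y.min() == y.max():
        raise FitError("outcome has a single class")
    idx = list(covariate_indices)
    X = np.column_stack([np.ones(cohort.n), cohort.x[:, idx]])
    if start is not None and len(start) == X.shape[1]:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(X.shape[1])
        # start the intercept at the logit of the event rate
        beta[0] = logit(y.mean())
    grad_norm = np.inf
    tol = GRADIENT_TOL * max(1.0, float(len(y)))
    for it in range(1, MAX_ITER + 1):
        lp = X @ beta
        p = expit(lp)
        grad = X.T @ (y - p)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm <= tol:
            return FittedModel(
                kind="logistic",
                covariate_indices=tuple(idx),
                coefficients=beta[1:].copy(),
                intercept=float(beta[0]),
                n_iter=it,
                gradient_norm=grad_norm,
            )
        w = p * (1.0 - p)
        h = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix at iteration {it} "
                f"(gradient norm {grad_norm:.3g}); data may be separated"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 40.0:
            raise SeparationError(
                f"diverging coefficients (max |beta| > 40) at iteration {it}; "
                "complete or quasi-complete separation"
            )
    raise FitError(
        f"logistic fit did not converge in {MAX_ITER} iterations "
        f"(gradient norm {grad_norm:.3g})"
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _cox_loglik_parts(beta, Xs, group_start, group_deaths, death_x_total):
    """Breslow partial log-likelihood, gradient and Hessian.

    Arrays are pre-sorted by ascending time; risk sets are suffix sums.
    ``group_start[k]`` is the first sorted index whose time >= the k-th
    distinct event time, ``group_deaths[k]`` the death count there, and
    ``death_x_total`` the covariate sum over all deaths.
    """
    lp = Xs @ beta
    shift = lp.max()
    w = np.exp(lp - shift)  # guard overflow; restored below
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # suffix cumulative sums (risk set = everyone with time >= t)
    s0g = np.cumsum(w[::-1])[::-1][group_start]
    s1g = np.cumsum(wx[::-1], axis=0)[::-1][group_start]
    s2g = np.cumsum(wxx[::-1], axis=0)[::-1][group_start]
    d = group_deaths.astype(float)
    # log S0_true = shift + log S0_shifted
    loglik = float(death_x_total @ beta - shift * d.sum() - np.sum(d * np.log(s0g)))
    mean1 = s1g / s0g[:, None]
    grad = death_x_total - (d[:, None] * mean1).sum(axis=0)
    hess = np.einsum("k,kij->ij", d, s2g / s0g[:, None, None]) - np.einsum(
        "k,ki,kj->ij", d, mean1, mean1
    )
    return loglik, grad, hess


def fit_cox(
    cohort: CohortData,
    covariate_indices: Sequence[int],
    horizon: Optional[float] = None,
    start: Optional[np.ndarray] = None,
) -> FittedModel:
    """Cox PH partial-likelihood fit with Breslow ties and baseline survival.

    The baseline survival at the horizon comes from the Breslow cumulative
    hazard ``H0(tau) = sum_{event times <= tau} d_k / S0(t_k)``.
    """
    if cohort.time is None:
        raise FitError("cohort has no observed times")
    y = np.asarray(cohort.y, dtype=np.int64)
    t = np.asarray(cohort.time, dtype=float)
    if np.any(t < 0):
        raise FitError("negative observed times")
    if y.sum() < 2:
        raise FitError("need at least 2 events")
    idx = list(covariate_indices)
    order = np.argsort(t, kind="stable")
    Xs = np.ascontiguousarray(cohort.x[order][:, idx], dtype=float)
    ts, ys = t[order], y[order]
    n, p = Xs.shape

    ev = ys == 1
    uniq_times, counts = np.unique(ts[ev], return_counts=True)
    # first sorted index at risk for each distinct event time
    group_start = np.searchsorted(ts, uniq_times, side="left")
    group_deaths = counts
    death_x_total = Xs[ev].sum(axis=0)

    if start is not None and len(start) == p:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(p)
    grad_norm = np.inf
    tol = GRADIENT_TOL * max(1.0, float(n))
    prev_ll = -np.inf
    prev_beta = beta
    step = np.zeros(p)
    halvings = 0
    it = 0
    while it < MAX_ITER:
        it += 1
        ll, grad, hess = _cox_loglik_parts(
            beta, Xs, group_start, group_deaths, death_x_total
        )
        if ll < prev_ll - 1e-12 and halvings < 30:
            # Newton overshoot: retreat half-way and re-evaluate
            halvings += 1
            beta = prev_beta + 0.5 * (beta - prev_beta)
            continue
        halvings = 0
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm <= tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular Hessian in Cox fit") from exc
        prev_ll, prev_beta = ll, beta
        beta = beta + step
        if np.max(np.abs(beta)) > 40.0:
            raise FitError("diverging Cox coefficients (monotone likelihood?)")
    else:
        raise FitError(
            f"Cox fit did not converge in {MAX_ITER} iterations "
            f"(gradient norm {grad_norm:.3g})"
        )

    tau = horizon if horizon is not None else float(ts.max())
    if tau > ts.max():
        raise FitError("horizon beyond the last observed time")
    lp = Xs @ beta
    w = np.exp(lp - lp.max())
    s0 = np.cumsum(w[::-1])[::-1] * np.exp(lp.max())
    within = uniq_times <= tau
    h0 = float(np.sum(group_deaths[within] / s0[group_start[within]]))
    return FittedModel(
        kind="cox",
        covariate_indices=tuple(idx),
        coefficients=beta.copy(),
        baseline_survival_at_tau=float(np.exp(-h0)),
        horizon=tau,
        n_iter=it,
        gradient_norm=grad_norm,
    )


# ---------------------------------------------------------------------------
# predictions and pairing
# ---------------------------------------------------------------------------

def predict_event_probability(
    model: FittedModel, cohort: CohortData, horizon: Optional[float] = None
) -> np.ndarray:
    """Per-subject predicted probability of the event (by the horizon).

    Logistic: inverse-logit of the linear predictor.  Cox:
    ``1 - S0(tau)**exp(linear predictor)``; strictly increasing in the risk
    score in both cases, so predictions and scores stay in one-to-one
    correspondence.
    """
    lp = model.linear_predictor(cohort.x)
    if model.kind == "logistic":
        return expit(model.intercept + lp)
    if model.kind == "cox":
        if horizon is not None and model.horizon is not None and horizon != model.horizon:
            raise ValueError(
                "model baseline survival was computed at a different horizon; refit"
            )
        s0 = model.baseline_survival_at_tau
        return 1.0 - np.exp(np.log(s0) * np.exp(lp))
    raise ValueError(f"unknown model kind {model.kind!r}")


def build_risk_pairs(
    cohort: CohortData,
    standard_model: FittedModel,
    expanded_model: FittedModel,
    horizon: Optional[float] = None,
) -> RiskPairs:
    """Pair the standard ('old') and expanded ('new') model predictions."""
    if not set(standard_model.covariate_indices) <= set(expanded_model.covariate_indices):
        raise ValueError("standard model must be nested in the expanded model")
    p_old = predict_event_probability(standard_model, cohort, horizon)
    p_new = predict_event_probability(expanded_model, cohort, horizon)
    if len(p_old) != len(p_new) or len(p_old) != cohort.n:
        raise ValueError("misaligned prediction vectors")
    return RiskPairs(
        y=np.asarray(cohort.y, dtype=np.int8),
        p_old=p_old,
        p_new=p_new,
        z_old=standard_model.linear_predictor(cohort.x),
        z_new=expanded_model.linear_predictor(cohort.x),
        time=cohort.time,
    )
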