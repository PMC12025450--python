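"""Confidence intervals: asymptotic formula and five bootstrap constructions.

The resampling engine is measure-agnostic: each replicate draws subjects
with replacement, refits *both* nested risk models on the resample, and
recomputes the measure(s).  Replicates where a fit or a measure is
undefined (single-class resample, empty movement group, degenerate
Kaplan-Meier denominator, ...) are skipped and logged, never redrawn; a
bootstrap distribution with fewer than 95% valid replicates is unusable.

Interval constructions: percentile, bias-corrected (BC), bias-corrected
and accelerated (BCa), bootstrap-t (studentized pivot), and hybrid (the
percentile interval reflected about the point estimate).  Empirical
quantiles use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import norm

from . import binary_measures as bm
from . import survival_measures as sm
from .binary_measures import MeasureError, MeasureEstimate
from .risk_models import FitError, build_risk_pairs, fit_cox, fit_logistic
from .synthetic_data import CohortData

__all__ = [
    "ModelSpec",
    "MeasureSpec",
    "BootstrapDistribution",
    "IntervalResult",
    "UnusableDistributionError",
    "evaluate_measures",
    "bootstrap_resample",
    "jackknife_estimates",
    "asymptotic_ci",
    "percentile_ci",
    "bc_ci",
    "bca_ci",
    "bootstrap_t_ci",
    "hybrid_ci",
]

MIN_VALID_FRACTION = 0.95
MIN_REPLICATES = 100


class UnusableDistributionError(RuntimeError):
    """Too few valid bootstrap replicates to form an interval."""


@dataclass(frozen=True)
class ModelSpec:
    """Which nested models to fit: standard vs expanded covariate sets."""

    framework: str  # "binary" | "survival"
    standard: tuple = (0,)
    expanded: tuple = (0, 4)
    horizon: Optional[float] = None  # survival only

    def __post_init__(self):
        if self.framework not in ("binary", "survival"):
            raise ValueError("framework must be 'binary' or 'survival'")
        if not set(self.standard) <= set(self.expanded):
            raise ValueError("standard model must be nested in the expanded model")
        if self.framework == "survival" and self.horizon is None:
            raise ValueError("survival framework requires a horizon")


@dataclass(frozen=True)
class MeasureSpec:
    """A named measure plus its options (category cutoffs, report label)."""

    name: str
    cutoffs: Optional[tuple] = None
    label: Optional[str] = None  # distinguishes e.g. 2- vs 3-category NRI

    _BINARY = ("delta_auc", "nri_cat", "nri_gt0", "idi")
    _SURVIVAL = ("delta_c", "nri_t_cat", "nri_t_cont", "idi_t")

    def __post_init__(self):
        if self.name not in self._BINARY + self._SURVIVAL:
            raise ValueError(f"unknown measure {self.name!r}")
        if self.name in ("nri_cat", "nri_t_cat") and not self.cutoffs:
            raise ValueError(f"{self.name} requires cutoffs")

    @property
    def key(self) -> str:
        return self.label if self.label is not None else self.name


def evaluate_measures(
    cohort: CohortData,
    model_spec: ModelSpec,
    measure_specs: Sequence[MeasureSpec],
    need_se: bool = True,
    warm_start: Optional[tuple] = None,
    return_models: bool = False,
):
    """Fit both nested models on the cohort and compute the measures.

    Raises :class:`FitError` / :class:`MeasureError` when undefined; the
    bootstrap engine turns those into skipped replicates.  ``need_se=False``
    skips standard errors that cost extra work (the DeLong components);
    ``warm_start=(standard, expanded)`` seeds the Newton iterations with
    previously fitted models; ``return_models`` appends the fitted pair to
    the return value.
    """
    w_old = w_new = None
    if warm_start is not None:
        w_old, w_new = warm_start
    if model_spec.framework == "binary":
        m_old = fit_logistic(
            cohort, model_spec.standard,
            start=None if w_old is None else np.r_[w_old.intercept, w_old.coefficients],
        )
        m_new = fit_logistic(
            cohort, model_spec.expanded,
            start=None if w_new is None else np.r_[w_new.intercept, w_new.coefficients],
        )
        pairs = build_risk_pairs(cohort, m_old, m_new)
    else:
        m_old = fit_cox(
            cohort, model_spec.standard, horizon=model_spec.horizon,
            start=None if w_old is None else w_old.coefficients,
        )
        m_new = fit_cox(
            cohort, model_spec.expanded, horizon=model_spec.horizon,
            start=None if w_new is None else w_new.coefficients,
        )
        pairs = build_risk_pairs(cohort, m_old, m_new)
    out = []
    for spec in measure_specs:
        if spec.name == "delta_auc":
            out.append(bm.delta_auc(pairs, with_se=need_se))
        elif spec.name == "nri_cat":
            out.append(bm.nri_categorical(bm.reclassify(pairs, spec.cutoffs)))
        elif spec.name == "nri_gt0":
            out.append(bm.nri_continuous(pairs))
        elif spec.name == "idi":
            out.append(bm.idi(pairs))
        elif spec.name == "delta_c":
            out.append(sm.delta_c(pairs))
        elif spec.name == "nri_t_cat":
            out.append(
                sm.nri_t(pairs, model_spec.horizon, "categorical", spec.cutoffs)
            )
        elif spec.name == "nri_t_cont":
            out.append(sm.nri_t(pairs, model_spec.horizon, "continuous"))
        elif spec.name == "idi_t":
            out.append(sm.idi_t(pairs, model_spec.horizon))
    if return_models:
        return out, (m_old, m_new)
    return out


# ---------------------------------------------------------------------------
# resampling engine
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDistribution:
    """Replicate estimates of one measure, with provenance."""

    measure: str
    point_estimate: float
    estimates: np.ndarray
    point_se: Optional[float] = None
    inner_ses: Optional[np.ndarray] = None
    b_requested: int = 0
    failure_log: dict = field(default_factory=dict)

    @property
    def b_valid(self) -> int:
        return len(self.estimates)

    @property
    def usable(self) -> bool:
        return (
            self.b_requested > 0
            and self.b_valid / self.b_requested >= MIN_VALID_FRACTION
        )

    def require_usable(self, minimum: int = MIN_REPLICATES):
        if self.b_valid < minimum or not self.usable:
            raise UnusableDistributionError(
                f"{self.b_valid}/{self.b_requested} valid replicates for "
                f"{self.measure}; failures: {self.failure_log}"
            )


def _replicate_seed(seed: int, b: int) -> np.random.Generator:
    # child b is addressable in isolation: results are independent of the
    # order in which replicates execute
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))


def _resample_indices(rng, y, n, stratified):
    if not stratified:
        return rng.integers(0, n, n)
    ev = np.flatnonzero(y == 1)
    ne = np.flatnonzero(y == 0)
    return np.concatenate(
        [ev[rng.integers(0, len(ev), len(ev))], ne[rng.integers(0, len(ne), len(ne))]]
    )


def _grouped_jackknife_se(
    cohort, model_spec, spec, n_groups: int, rng
) -> float:
    """Delete-d jackknife SE for measures without an analytic SE formula."""
    n = cohort.n
    perm = rng.permutation(n)
    groups = np.array_split(perm, n_groups)
    vals = []
    for g in groups:
        mask = np.ones(n, dtype=bool)
        mask[g] = False
        est = evaluate_measures(cohort.subset(np.flatnonzero(mask)), model_spec, [spec])
        vals.append(est[0].value)
    vals = np.asarray(vals)
    g = len(vals)
    return float(np.sqrt((g - 1) / g * np.sum((vals - vals.mean()) ** 2)))


def bootstrap_resample(
    cohort: CohortData,
    model_spec: ModelSpec,
    measure_spec,
    B: int,
    seed: int,
    stratified: bool = False,
    compute_inner_se: bool = False,
    inner_jackknife_groups: int = 25,
):
    """Bootstrap the measure(s) with full nested-model refitting.

    ``measure_spec`` may be one :class:`MeasureSpec` or a sequence; a single
    spec returns one :class:`BootstrapDistribution`, a sequence returns a
    dict keyed by measure name (all measures share the same resamples, so
    model fitting is paid once per replicate).

    With ``compute_inner_se`` the per-replicate SE needed by the
    bootstrap-t interval is recorded: the asymptotic formula SE where one
    exists, otherwise a grouped (delete-d) jackknife within the resample.
    """
    single = isinstance(measure_spec, MeasureSpec)
    specs = [measure_spec] if single else list(measure_spec)
    if B < MIN_REPLICATES:
        raise ValueError(f"B must be at least {MIN_REPLICATES}")
    # drop unused covariate columns: resampling copies the matrix B times
    cols = sorted(set(model_spec.standard) | set(model_spec.expanded))
    remap = {c: i for i, c in enumerate(cols)}
    model_spec = ModelSpec(
        framework=model_spec.framework,
        standard=tuple(remap[c] for c in model_spec.standard),
        expanded=tuple(remap[c] for c in model_spec.expanded),
        horizon=model_spec.horizon,
    )
    cohort = CohortData(
        y=np.asarray(cohort.y), x=np.ascontiguousarray(cohort.x[:, cols]),
        time=cohort.time,
    )
    point_ests, warm = evaluate_measures(
        cohort, model_spec, specs, return_models=True
    )
    point = {s.key: e for s, e in zip(specs, point_ests)}
    if compute_inner_se:
        # measures without an analytic SE need one on the original sample
        # too (the bootstrap-t denominator); use the same grouped jackknife
        se_rng = _replicate_seed(seed, 2**32 - 1)  # reserved key, off the 0..B-1 range
        for s, e in zip(specs, point_ests):
            if e.se is None or not np.isfinite(e.se):
                e.se = _grouped_jackknife_se(
                    cohort, model_spec, s, inner_jackknife_groups, se_rng
                )
    n = cohort.n
    y = np.asarray(cohort.y)
    values = {s.key: [] for s in specs}
    ses = {s.key: [] for s in specs}
    failures = {s.key: {} for s in specs}
    for b in range(B):
        rng = _replicate_seed(seed, b)
        idx = _resample_indices(rng, y, n, stratified)
        sub = cohort.subset(idx)
        try:
            ests = evaluate_measures(
                sub, model_spec, specs,
                need_se=compute_inner_se, warm_start=warm,
            )
        except (FitError, MeasureError) as exc:
            key = type(exc).__name__
            for s in specs:
                failures[s.key][key] = failures[s.key].get(key, 0) + 1
            continue
        for s, e in zip(specs, ests):
            se_b = e.se
            if compute_inner_se and (se_b is None or not np.isfinite(se_b)):
                try:
                    se_b = _grouped_jackknife_se(
                        sub, model_spec, s, inner_jackknife_groups, rng
                    )
                except (FitError, MeasureError):
                    se_b = np.nan
            values[s.key].append(e.value)
            ses[s.key].append(np.nan if se_b is None else se_b)
    out = {}
    for s in specs:
        pe = point[s.key]
        out[s.key] = BootstrapDistribution(
            measure=s.key,
            point_estimate=pe.value,
            point_se=pe.se,
            estimates=np.asarray(values[s.key], dtype=float),
            inner_ses=np.asarray(ses[s.key], dtype=float)
            if compute_inner_se
            else None,
            b_requested=B,
            failure_log=failures[s.key],
        )
    return out[specs[0].key] if single else out


def jackknife_estimates(
    cohort: CohortData, model_spec: ModelSpec, measure_spec: MeasureSpec
) -> np.ndarray:
    """Leave-one-out estimates on the original cohort (for the BCa interval)."""
    n = cohort.n
    vals = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        sub = cohort.subset(np.delete(all_idx, i))
        vals[i] = evaluate_measures(sub, model_spec, [measure_spec])[0].value
    return vals


# ---------------------------------------------------------------------------
# interval constructions
# ---------------------------------------------------------------------------

@dataclass
class IntervalResult:
    method: str
    lower: float
    upper: float
    alpha: float
    measure: str = ""

    @property
    def level(self) -> float:
        return 1.0 - 2.0 * self.alpha

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, theta: float) -> bool:
        return self.lower <= theta <= self.upper


def _quantile(est: np.ndarray, q) -> np.ndarray:
    # linear interpolation between order statistics (Hyndman-Fan type 7)
    return np.quantile(est, q, method="linear")


def asymptotic_ci(estimate: MeasureEstimate, alpha: float = 0.025) -> IntervalResult:
    """Normal-theory interval theta-hat +/- z_{1-alpha} * SE."""
    if estimate.se is None or not np.isfinite(estimate.se):
        raise ValueError(
            f"measure {estimate.name!r} carries no asymptotic SE; "
            "use a bootstrap interval"
        )
    z = norm.ppf(1.0 - alpha)
    return IntervalResult(
        method="asymptotic",
        lower=float(estimate.value - z * estimate.se),
        upper=float(estimate.value + z * estimate.se),
        alpha=alpha,
        measure=estimate.name,
    )


def percentile_ci(dist: BootstrapDistribution, alpha: float = 0.025) -> IntervalResult:
    """Raw empirical quantiles (q_alpha, q_{1-alpha}) of the replicates."""
    dist.require_usable()
    lo, hi = _quantile(dist.estimates, [alpha, 1.0 - alpha])
    return IntervalResult("percentile", float(lo), float(hi), alpha, dist.measure)


def bc_ci(dist: BootstrapDistribution, alpha: float = 0.025) -> IntervalResult:
    """Bias-corrected percentile: quantile levels shifted by 2 z0.

    z0 = Phi^{-1}(fraction of replicates strictly below the point
    estimate); the endpoints are the empirical quantiles at
    Phi(2 z0 + z_alpha) and Phi(2 z0 + z_{1-alpha}).
    """
    dist.require_usable()
    frac = float((dist.estimates < dist.point_estimate).mean())
    if frac <= 0.0 or frac >= 1.0:
        raise UnusableDistributionError(
            "all replicates on one side of the point estimate; z0 is infinite"
        )
    z0 = norm.ppf(frac)
    lv = norm.cdf(2.0 * z0 + norm.ppf([alpha, 1.0 - alpha]))
    lo, hi = _quantile(dist.estimates, lv)
    return IntervalResult("bc", float(lo), float(hi), alpha, dist.measure)


def bca_ci(
    dist: BootstrapDistribution,
    jackknife_values: np.ndarray,
    alpha: float = 0.025,
) -> IntervalResult:
    """Bias-corrected and accelerated percentile interval.

    Acceleration from the jackknife skewness formula
    a = sum (mean - v_i)^3 / (6 [sum (mean - v_i)^2]^{3/2}).
    """
    dist.require_usable()
    frac = float((dist.estimates < dist.point_estimate).mean())
    if frac <= 0.0 or frac >= 1.0:
        raise UnusableDistributionError(
            "all replicates on one side of the point estimate; z0 is infinite"
        )
    z0 = norm.ppf(frac)
    jv = np.asarray(jackknife_values, dtype=float)
    dev = jv.mean() - jv
    ss = np.sum(dev**2)
    if ss <= 0.0 or np.max(np.abs(dev)) <= 1e-12 * (1.0 + abs(jv.mean())):
        raise UnusableDistributionError("degenerate jackknife variance")
    a = np.sum(dev**3) / (6.0 * ss**1.5)
    z = norm.ppf([alpha, 1.0 - alpha])
    lv = norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lo, hi = _quantile(dist.estimates, lv)
    return IntervalResult("bca", float(lo), float(hi), alpha, dist.measure)


def bootstrap_t_ci(dist: BootstrapDistribution, alpha: float = 0.025) -> IntervalResult:
    """Studentized-pivot interval.

    Pivots t*_b = (theta*_b - theta-hat) / se*_b; endpoints
    theta-hat - t*_{1-alpha} * se  and  theta-hat - t*_alpha * se with the
    original-sample SE.  Replicates with a zero or missing inner SE are
    skipped (logged into the usability accounting).
    """
    if dist.inner_ses is None:
        raise ValueError("bootstrap-t requires per-replicate inner SEs")
    if dist.point_se is None or not np.isfinite(dist.point_se):
        raise ValueError("bootstrap-t requires an SE for the original estimate")
    ok = np.isfinite(dist.inner_ses) & (dist.inner_ses > 0.0)
    n_ok = int(ok.sum())
    if dist.b_requested and n_ok / dist.b_requested < MIN_VALID_FRACTION:
        raise UnusableDistributionError(
            f"only {n_ok}/{dist.b_requested} replicates have a positive inner SE"
        )
    if n_ok < MIN_REPLICATES:
        raise UnusableDistributionError("too few studentizable replicates")
    t = (dist.estimates[ok] - dist.point_estimate) / dist.inner_ses[ok]
    t_lo, t_hi = _quantile(t, [alpha, 1.0 - alpha])
    return IntervalResult(
        "bootstrap_t",
        float(dist.point_estimate - t_hi * dist.point_se),
        float(dist.point_estimate - t_lo * dist.point_se),
        alpha,
        dist.measure,
    )


def hybrid_ci(dist: BootstrapDistribution, alpha: float = 0.025) -> IntervalResult:
    """Percentile endpoints reflected about the point estimate:
    (2 theta-hat - q_{1-alpha}, 2 theta-hat - q_alpha)."""
    dist.require_usable()
    lo_q, hi_q = _quantile(dist.estimates, [alpha, 1.0 - alpha])
    return IntervalResult(
        "hybrid",
        float(2.0 * dist.point_estimate - hi_q),
        float(2.0 * dist.point_estimate - lo_q),
        alpha,
        dist.measure,
    )
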