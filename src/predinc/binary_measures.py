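"""Binary-framework prediction-increment measures and asymptotic SEs.

Implements the Mann-Whitney C-statistic (AUC), the DeLong
structural-component standard error for the paired AUC difference, the
categorical and continuous net reclassification improvement (NRI) with
their large-sample standard errors, and the integrated discrimination
improvement (IDI) with the paired-difference standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .risk_models import RiskPairs

__all__ = [
    "MeasureEstimate",
    "ReclassificationTable",
    "MeasureError",
    "c_statistic",
    "delta_auc",
    "reclassify",
    "nri_categorical",
    "nri_continuous",
    "idi",
    "default_cutoffs",
]


class MeasureError(ValueError):
    """A measure is undefined on the given input (e.g. a single-class sample)."""


@dataclass
class MeasureEstimate:
    """A named statistic with an optional asymptotic standard error."""

    name: str
    value: float
    se: Optional[float] = None
    n_events: int = 0
    n_nonevents: int = 0
    metadata: dict = field(default_factory=dict)


def default_cutoffs(event_rate: float, n_categories: int = 2) -> tuple:
    """Risk-category boundaries used throughout the simulations.

    Two categories: single cutoff at the event rate.  Three categories:
    (0.05, 0.20) for the 10% event rate and (0.40, 0.60) for the 50% rate.
    """
    if n_categories == 2:
        return (float(event_rate),)
    if n_categories == 3:
        if abs(event_rate - 0.10) < 1e-9:
            return (0.05, 0.20)
        if abs(event_rate - 0.50) < 1e-9:
            return (0.40, 0.60)
        raise ValueError("no conventional 3-category bands for this event rate")
    raise ValueError("n_categories must be 2 or 3")


# ---------------------------------------------------------------------------
# C-statistic / AUC
# ---------------------------------------------------------------------------

def midranks(a: np.ndarray) -> np.ndarray:
    """1-based midranks (ties get the average of their positions).

    Equivalent to ``scipy.stats.rankdata(a, method='average')``; local
    implementation because the AUC machinery sits on the bootstrap hot
    path, where the scipy wrapper's overhead dominates.
    """
    a = np.asarray(a)
    order = np.argsort(a, kind="stable")
    s = a[order]
    bounds = np.empty(len(s) + 1, dtype=bool)
    bounds[0] = bounds[-1] = True
    np.not_equal(s[1:], s[:-1], out=bounds[1:-1])
    edges = np.flatnonzero(bounds)
    avg = 0.5 * (edges[:-1] + edges[1:] + 1.0)  # midrank of each tie group
    out = np.empty(len(s))
    out[order] = np.repeat(avg, np.diff(edges))
    return out


def c_statistic(risks: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for tied risks.

    Equals (1 / n0 n1) * sum over nonevent x event pairs of
    1{risk_nonevent < risk_event} + 0.5 * 1{tie}; computed via midranks in
    O(n log n).  Invariant under strictly increasing transforms.
    """
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise MeasureError("both outcome classes must be present")
    r = midranks(risks)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def _delong_placements(risks: np.ndarray, y: np.ndarray):
    """Structural components V10 (events) and V01 (nonevents).

    V10_i = P-hat(nonevent risk < risk_i) + 0.5 P-hat(tie), via midranks
    in the pooled sample and within each class.
    """
    risks = np.asarray(risks, dtype=float)
    ev = y == 1
    n1, n0 = int(ev.sum()), int((~ev).sum())
    r_all = midranks(risks)
    r_ev = midranks(risks[ev])
    r_ne = midranks(risks[~ev])
    v10 = (r_all[ev] - r_ev) / n0
    v01 = 1.0 - (r_all[~ev] - r_ne) / n1
    return v10, v01


def delta_auc(pairs: RiskPairs, with_se: bool = True) -> MeasureEstimate:
    """Paired AUC difference with the DeLong standard error.

    SE(dAUC) = sqrt((1,-1) S (1,-1)') where S is the estimated 2x2
    covariance of the two correlated AUC estimates, built from the
    structural components of each model's predictions.  ``with_se=False``
    skips the structural components (the bootstrap percentile path only
    needs the value).
    """
    y = pairs.y
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise MeasureError("both outcome classes must be present")
    if not with_se:
        auc_new = c_statistic(pairs.p_new, y)
        auc_old = c_statistic(pairs.p_old, y)
        return MeasureEstimate(
            name="delta_auc", value=auc_new - auc_old, se=None,
            n_events=n1, n_nonevents=n0,
            metadata={"auc_new": auc_new, "auc_old": auc_old},
        )
    v10_new, v01_new = _delong_placements(pairs.p_new, y)
    v10_old, v01_old = _delong_placements(pairs.p_old, y)
    auc_new = float(v10_new.mean())
    auc_old = float(v10_old.mean())
    d10 = v10_new - v10_old
    d01 = v01_new - v01_old
    if n1 > 1 and n0 > 1:
        var = d10.var(ddof=1) / n1 + d01.var(ddof=1) / n0
    else:
        var = np.nan
    return MeasureEstimate(
        name="delta_auc",
        value=auc_new - auc_old,
        se=float(np.sqrt(max(var, 0.0))),
        n_events=n1,
        n_nonevents=n0,
        metadata={"auc_new": auc_new, "auc_old": auc_old},
    )


# ---------------------------------------------------------------------------
# reclassification / NRI
# ---------------------------------------------------------------------------

@dataclass
class ReclassificationTable:
    """Old-category x new-category cross-tabulation, split by outcome."""

    cutoffs: tuple
    counts_events: np.ndarray  # k x k
    counts_nonevents: np.ndarray  # k x k

    @property
    def n_events(self) -> int:
        return int(self.counts_events.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.counts_nonevents.sum())

    def _movement(self, counts: np.ndarray):
        up = int(np.triu(counts, k=1).sum())
        down = int(np.tril(counts, k=-1).sum())
        same = int(np.trace(counts))
        return up, down, same

    @property
    def events_up_down_same(self):
        return self._movement(self.counts_events)

    @property
    def nonevents_up_down_same(self):
        return self._movement(self.counts_nonevents)


def assign_categories(p: np.ndarray, cutoffs: Sequence[float]) -> np.ndarray:
    """Category index by half-open intervals [low, high)."""
    return np.searchsorted(np.asarray(cutoffs, dtype=float), p, side="right")


def reclassify(pairs: RiskPairs, cutoffs: Sequence[float]) -> ReclassificationTable:
    """Cross-tabulate old vs new risk categories, events and nonevents apart."""
    cutoffs = tuple(float(c) for c in cutoffs)
    if len(cutoffs) == 0:
        raise MeasureError("at least one category cutoff is required")
    if any(c2 <= c1 for c1, c2 in zip(cutoffs, cutoffs[1:])):
        raise MeasureError("cutoffs must be strictly increasing")
    if not all(0.0 < c < 1.0 for c in cutoffs):
        raise MeasureError("cutoffs must lie strictly inside (0, 1)")
    k = len(cutoffs) + 1
    old = assign_categories(pairs.p_old, cutoffs)
    new = assign_categories(pairs.p_new, cutoffs)
    flat = old * k + new
    ev = pairs.y == 1
    ce = np.bincount(flat[ev], minlength=k * k).reshape(k, k)
    cn = np.bincount(flat[~ev], minlength=k * k).reshape(k, k)
    return ReclassificationTable(cutoffs=cutoffs, counts_events=ce, counts_nonevents=cn)


def _nri_from_proportions(p_up1, p_down1, p_up0, p_down0, n1, n0, name):
    enri = p_up1 - p_down1
    nenri = p_down0 - p_up0
    se_e = np.sqrt(max((p_up1 + p_down1) / n1 - enri**2 / n1, 0.0))
    se_ne = np.sqrt(max((p_down0 + p_up0) / n0 - nenri**2 / n0, 0.0))
    se = float(np.sqrt(se_e**2 + se_ne**2))
    return MeasureEstimate(
        name=name,
        value=float(enri + nenri),
        se=se,
        n_events=n1,
        n_nonevents=n0,
        metadata={
            "enri": float(enri),
            "nenri": float(nenri),
            "se_enri": float(se_e),
            "se_nenri": float(se_ne),
            "p_up_events": float(p_up1),
            "p_down_events": float(p_down1),
            "p_up_nonevents": float(p_up0),
            "p_down_nonevents": float(p_down0),
        },
    )


def nri_categorical(table: ReclassificationTable) -> MeasureEstimate:
    """Categorical NRI = eNRI + neNRI with the large-sample SEs.

    eNRI = P-hat(up|event) - P-hat(down|event);
    neNRI = P-hat(down|nonevent) - P-hat(up|nonevent);
    SE(eNRI) = sqrt((p_up + p_down)/n1 - (p_up - p_down)^2/n1), and the
    combined SE adds the class components in quadrature.
    """
    n1, n0 = table.n_events, table.n_nonevents
    if n1 == 0 or n0 == 0:
        raise MeasureError("both outcome classes must be present")
    up1, down1, _ = table.events_up_down_same
    up0, down0, _ = table.nonevents_up_down_same
    est = _nri_from_proportions(
        up1 / n1, down1 / n1, up0 / n0, down0 / n0, n1, n0, "nri_cat"
    )
    est.metadata["cutoffs"] = table.cutoffs
    return est


def nri_continuous(pairs: RiskPairs) -> MeasureEstimate:
    """Continuous NRI (NRI > 0): strict risk increases vs decreases.

    Exact ties p_new == p_old count as neither direction.
    """
    ev = pairs.y == 1
    n1, n0 = int(ev.sum()), int((~ev).sum())
    if n1 == 0 or n0 == 0:
        raise MeasureError("both outcome classes must be present")
    up = pairs.p_new > pairs.p_old
    down = pairs.p_new < pairs.p_old
    return _nri_from_proportions(
        up[ev].mean(), down[ev].mean(), up[~ev].mean(), down[~ev].mean(),
        n1, n0, "nri_gt0",
    )


# ---------------------------------------------------------------------------
# IDI
# ---------------------------------------------------------------------------

def idi(pairs: RiskPairs) -> MeasureEstimate:
    """Integrated discrimination improvement with paired-difference SE.

    IDI-hat = (mean p_new - mean p_old | events)
            - (mean p_new - mean p_old | nonevents),
    equivalently the difference in discrimination slopes.  Each class SE is
    the standard error of the within-class paired differences (sample
    variance, n-1 divisor), combined in quadrature.
    """
    ev = pairs.y == 1
    n1, n0 = int(ev.sum()), int((~ev).sum())
    if n1 == 0 or n0 == 0:
        raise MeasureError("both outcome classes must be present")
    d = pairs.p_new - pairs.p_old
    mean_ev, mean_ne = float(d[ev].mean()), float(d[~ev].mean())
    se_ev = d[ev].std(ddof=1) / np.sqrt(n1) if n1 > 1 else np.nan
    se_ne = d[~ev].std(ddof=1) / np.sqrt(n0) if n0 > 1 else np.nan
    return MeasureEstimate(
        name="idi",
        value=mean_ev - mean_ne,
        se=float(np.sqrt(se_ev**2 + se_ne**2)),
        n_events=n1,
        n_nonevents=n0,
        metadata={"mean_diff_events": mean_ev, "mean_diff_nonevents": mean_ne},
    )
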