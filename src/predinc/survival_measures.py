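"""Survival-framework prediction-increment measures.

Overall C (Harrell's concordance over usable pairs) and its paired
difference dC, Kaplan-Meier based NRI(t) in categorical and continuous
modes, and IDI(t) as the difference of explained-variance ratios R^2(t).

The concordance estimator is O(n log n): subjects are processed in
decreasing observed-time order while a Fenwick tree indexed by prediction
rank counts, for each event, how many later-surviving subjects received a
lower / equal / higher predicted risk.  A brute-force pair enumeration
serves as the oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .binary_measures import MeasureError, MeasureEstimate, assign_categories
from .risk_models import RiskPairs

__all__ = [
    "KaplanMeierCurve",
    "kaplan_meier",
    "overall_c",
    "delta_c",
    "nri_t",
    "r_squared_t",
    "idi_t",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit estimator as a right-continuous step function."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S-hat just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step value at the largest event time <= t (1.0 before the first)."""
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> KaplanMeierCurve:
    """Product-limit survival estimate.

    Ties between events and censorings at the same time follow the usual
    convention: censored subjects at time t remain in the risk set for the
    deaths at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if len(times) == 0:
        raise MeasureError("empty input")
    if np.any(times < 0):
        raise MeasureError("negative times")
    order = np.argsort(times, kind="stable")
    ts, ev = times[order], events[order]
    uniq, first = np.unique(ts, return_index=True)
    n = len(ts)
    at_risk_all = n - first  # subjects with time >= uniq[k]
    d = np.add.reduceat(ev.astype(np.int64), first)
    has_event = d > 0
    et = uniq[has_event]
    dk = d[has_event]
    rk = at_risk_all[has_event]
    surv = np.cumprod(1.0 - dk / rk)
    return KaplanMeierCurve(
        event_times=et, survival=surv, at_risk=rk, n_events=dk
    )


# ---------------------------------------------------------------------------
# overall C
# ---------------------------------------------------------------------------

@njit(cache=False)
def _concordance_counts(time_order_desc, is_event, pred_rank, n_ranks, tie_credit):
    """Numerator (with 0.5 tie credit) and pair count over usable pairs.

    Subjects arrive in strictly decreasing observed-time order, grouped so
    that equal times are inserted together *after* the group is scored:
    pairs with tied observed times are not usable.  For an event at time t,
    every already-inserted subject has a strictly larger observed time; the
    pair is concordant when that subject's predicted risk is lower.
    """
    n = len(time_order_desc)
    tree = np.zeros(n_ranks + 1, dtype=np.float64)
    inserted = 0
    num = 0.0
    q = 0.0
    i = 0
    while i < n:
        j = i
        # group of equal times (time_order_desc pre-sorted descending)
        while j + 1 < n and time_order_desc[j + 1] == time_order_desc[i]:
            j += 1
        for k in range(i, j + 1):
            if is_event[k]:
                r = pred_rank[k]
                # count inserted with rank < r (strictly lower risk)
                s = 0.0
                idx = r - 1
                while idx > 0:
                    s += tree[idx]
                    idx -= idx & (-idx)
                s_le = 0.0
                idx = r
                while idx > 0:
                    s_le += tree[idx]
                    idx -= idx & (-idx)
                ties = s_le - s
                num += s + tie_credit * ties
                q += inserted
        for k in range(i, j + 1):
            idx = pred_rank[k]
            while idx <= n_ranks:
                tree[idx] += 1.0
                idx += idx & (-idx)
            inserted += 1
        i = j + 1
    return num, q


def overall_c(
    predictions: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    tie_credit: float = 0.5,
) -> MeasureEstimate:
    """Harrell's overall C over usable pairs.

    A pair is usable when the smaller observed time is an event time and
    the times differ; the pair is concordant when the shorter-lived subject
    was assigned the higher predicted risk.  Prediction ties score
    ``tie_credit`` (0.5 by default; 0.0 gives the strict concordant-or-not
    convention, which only differs on tied predictions — a measure-zero
    event for continuous risk scores).
    """
    predictions = np.asarray(predictions, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(np.bool_)
    order = np.argsort(-times, kind="stable")
    ranks = np.unique(predictions, return_inverse=True)[1] + 1
    num, q = _concordance_counts(
        times[order],
        events[order],
        ranks[order].astype(np.int64),
        int(ranks.max()),
        float(tie_credit),
    )
    if q == 0:
        raise MeasureError("no usable pairs")
    n1 = int(events.sum())
    return MeasureEstimate(
        name="overall_c",
        value=float(num / q),
        se=None,
        n_events=n1,
        n_nonevents=len(times) - n1,
        metadata={"usable_pairs": float(q)},
    )


def delta_c(pairs: RiskPairs) -> MeasureEstimate:
    """dC = C(expanded) - C(standard) over the same usable-pair set."""
    if pairs.time is None:
        raise MeasureError("risk pairs carry no observed times")
    ev = np.asarray(pairs.y).astype(bool)
    c_new = overall_c(pairs.p_new, pairs.time, ev)
    c_old = overall_c(pairs.p_old, pairs.time, ev)
    return MeasureEstimate(
        name="delta_c",
        value=c_new.value - c_old.value,
        se=None,
        n_events=c_new.n_events,
        n_nonevents=c_new.n_nonevents,
        metadata={"c_new": c_new.value, "c_old": c_old.value},
    )


# ---------------------------------------------------------------------------
# NRI(t)
# ---------------------------------------------------------------------------

def _movement_groups(pairs: RiskPairs, mode: str, cutoffs) -> np.ndarray:
    """+1 for upward movement, -1 for downward, 0 for no change."""
    if mode == "categorical":
        if cutoffs is None:
            raise MeasureError("categorical mode requires cutoffs")
        old = assign_categories(pairs.p_old, cutoffs)
        new = assign_categories(pairs.p_new, cutoffs)
        return np.sign(new - old).astype(np.int8)
    if mode == "continuous":
        return np.sign(pairs.p_new - pairs.p_old).astype(np.int8)
    raise ValueError("mode must be 'categorical' or 'continuous'")


def _km_event_prob(times, events, horizon) -> float:
    """1 - S-hat(horizon) within a subgroup; 0 for an empty subgroup."""
    if len(times) == 0:
        return 0.0
    return 1.0 - kaplan_meier(times, events).survival_at(horizon)


def nri_t(
    pairs: RiskPairs,
    horizon: float,
    mode: str = "categorical",
    cutoffs: Optional[Sequence[float]] = None,
    weight: float = 0.5,
    estimator: str = "km",
) -> MeasureEstimate:
    """Survival NRI at the horizon, doubled from the w = 0.5 weighting.

    Subjects are classified by risk movement under the expanded model;
    subgroup event probabilities P(Y(t)=1 | Z_up), P(Y(t)=1 | Z_down) and
    the marginal p = P(Y(t)=1) are Kaplan-Meier estimates (``estimator=
    'km'``) or raw event-indicator proportions (``estimator='count'``,
    valid without censoring).  With the default weight 0.5 the value is

      2 * [ (P(Y=1|Z_up) - p) P(Z_up) - (P(Y=1|Z_down) - p) P(Z_down) ]
        / (p (1 - p)),

    which reduces to the binary eNRI + neNRI form when censoring vanishes.
    A non-default weight w returns
    2 * [w * NRI_events(t) + (1 - w) * NRI_nonevents(t)].
    """
    if pairs.time is None:
        raise MeasureError("risk pairs carry no observed times")
    move = _movement_groups(pairs, mode, cutoffs)
    n = pairs.n
    p_up_frac = float((move == 1).sum()) / n
    p_down_frac = float((move == -1).sum()) / n
    if estimator == "km":
        p1_up = _km_event_prob(pairs.time[move == 1], pairs.y[move == 1], horizon)
        p1_down = _km_event_prob(pairs.time[move == -1], pairs.y[move == -1], horizon)
        p_marg = _km_event_prob(pairs.time, pairs.y, horizon)
    elif estimator == "count":
        ev_by_t = (pairs.y == 1) & (pairs.time <= horizon)
        up, down = move == 1, move == -1
        p1_up = float(ev_by_t[up].mean()) if up.any() else 0.0
        p1_down = float(ev_by_t[down].mean()) if down.any() else 0.0
        p_marg = float(ev_by_t.mean())
    else:
        raise ValueError("estimator must be 'km' or 'count'")
    if p_marg <= 0.0 or p_marg >= 1.0:
        raise MeasureError("marginal event probability at the horizon is degenerate")
    nri_events = (p1_up * p_up_frac - p1_down * p_down_frac) / p_marg
    nri_nonevents = (
        (1.0 - p1_down) * p_down_frac - (1.0 - p1_up) * p_up_frac
    ) / (1.0 - p_marg)
    value = 2.0 * (weight * nri_events + (1.0 - weight) * nri_nonevents)
    name = "nri_t_cat" if mode == "categorical" else "nri_t_cont"
    return MeasureEstimate(
        name=name,
        value=float(value),
        se=None,
        n_events=int((pairs.y == 1).sum()),
        n_nonevents=int((pairs.y == 0).sum()),
        metadata={
            "horizon": horizon,
            "weight": weight,
            "estimator": estimator,
            "p_event_up": p1_up,
            "p_event_down": p1_down,
            "p_event_marginal": p_marg,
            "p_up": p_up_frac,
            "p_down": p_down_frac,
            "nri_events": float(nri_events),
            "nri_nonevents": float(nri_nonevents),
            "cutoffs": None if cutoffs is None else tuple(cutoffs),
        },
    )


# ---------------------------------------------------------------------------
# R^2(t) and IDI(t)
# ---------------------------------------------------------------------------

def r_squared_t(
    predictions_survival: np.ndarray, km: KaplanMeierCurve, horizon: float
) -> float:
    """Explained-variance ratio Var[S(t|Z)] / (S-hat(t) (1 - S-hat(t))).

    ``predictions_survival`` are the model-based survival probabilities
    S(t|Z) at the horizon; S-hat is the marginal Kaplan-Meier value.
    Sample variance uses the n-1 divisor.  Theoretically bounded by [0, 1];
    a value above 1 (possible in small samples) is returned as computed.
    """
    s = np.asarray(predictions_survival, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise MeasureError("survival predictions must lie in [0, 1]")
    s_marg = km.survival_at(horizon)
    denom = s_marg * (1.0 - s_marg)
    if denom <= 0.0:
        raise MeasureError("degenerate marginal survival at the horizon")
    return float(s.var(ddof=1) / denom)


def idi_t(pairs: RiskPairs, horizon: float) -> MeasureEstimate:
    """IDI(t) = R^2(t) of the expanded model minus that of the standard model."""
    if pairs.time is None:
        raise MeasureError("risk pairs carry no observed times")
    km = kaplan_meier(pairs.time, pairs.y)
    r2_new = r_squared_t(1.0 - pairs.p_new, km, horizon)
    r2_old = r_squared_t(1.0 - pairs.p_old, km, horizon)
    return MeasureEstimate(
        name="idi_t",
        value=r2_new - r2_old,
        se=None,
        n_events=int((pairs.y == 1).sum()),
        n_nonevents=int((pairs.y == 0).sum()),
        metadata={"r2_new": r2_new, "r2_old": r2_old, "horizon": horizon},
    )
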