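"""Independent brute-force oracles and small builders shared by the tests.

Everything here is deliberately naive (double loops, explicit products) so
it cannot share a code path — or a bug — with the package implementations.
"""

import numpy as np

from predinc import RiskPairs


def make_pairs(y, p_old, p_new, time=None):
    y = np.asarray(y)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    return RiskPairs(
        y=y, p_old=p_old, p_new=p_new, z_old=p_old.copy(), z_new=p_new.copy(),
        time=None if time is None else np.asarray(time, dtype=float),
    )


def c_stat_brute(risks, y):
    """AUC by exhaustive nonevent x event pair enumeration."""
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(y)
    ev = risks[y == 1]
    ne = risks[y == 0]
    total = 0.0
    for a in ne:
        for b in ev:
            if a < b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(ev) * len(ne))


def delong_brute(p_model, y):
    """Structural components by double loops: V10 per event, V01 per nonevent."""
    p_model = np.asarray(p_model, dtype=float)
    ev = p_model[y == 1]
    ne = p_model[y == 0]
    v10 = np.array(
        [np.mean((ne < b) + 0.5 * (ne == b)) for b in ev]
    )
    v01 = np.array(
        [np.mean((a < ev) + 0.5 * (a == ev)) for a in ne]
    )
    return v10, v01


def delta_auc_se_brute(p_old, p_new, y):
    """DeLong SE of the paired AUC difference from brute-force components."""
    v10n, v01n = delong_brute(p_new, y)
    v10o, v01o = delong_brute(p_old, y)
    n1, n0 = len(v10n), len(v01n)
    s10 = np.cov(np.vstack([v10n, v10o]), ddof=1)
    s01 = np.cov(np.vstack([v01n, v01o]), ddof=1)
    s = s10 / n1 + s01 / n0
    var = s[0, 0] + s[1, 1] - 2.0 * s[0, 1]
    return float(v10n.mean() - v10o.mean()), float(np.sqrt(max(var, 0.0)))


def harrell_c_brute(pred, time, event):
    """Concordance by enumerating every pair.

    Usable: distinct observed times and the earlier one is an event.
    Concordant: the earlier (shorter-lived) subject has the higher
    predicted risk; prediction ties get 0.5.
    """
    pred = np.asarray(pred, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    num = q = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            a, b = (i, j) if time[i] < time[j] else (j, i)
            if not event[a]:
                continue
            q += 1
            if pred[a] > pred[b]:
                num += 1.0
            elif pred[a] == pred[b]:
                num += 0.5
    return num, q


def km_survival_brute(times, events, t):
    """Product-limit estimate at t by an explicit product over event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    s = 1.0
    for u in np.unique(times[events]):
        if u > t:
            break
        d = np.sum(events & (times == u))
        r = np.sum(times >= u)
        s *= 1.0 - d / r
    return s


def quantile_linear(values, level):
    """Type-7 quantile via explicit order-statistic interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (len(v) - 1) * level
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1.0 - frac) + v[hi] * frac
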