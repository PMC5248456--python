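"""Independent brute-force oracles used to cross-check the implementation.

Each function here is written directly from the defining formula (loops, pair
enumeration, 1-D likelihood search) and deliberately shares no code with the
package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar


def bh_oracle(p):
    """Step-up BH by definition: q_(i) = min_{j>=i} p_(j)*n/j, capped at 1."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q_sorted = [0.0] * n
    for rank_i in range(n):
        q_sorted[rank_i] = min(
            min(p[order[j]] * n / (j + 1) for j in range(rank_i, n)), 1.0
        )
    q = [0.0] * n
    for rank_i, idx in enumerate(order):
        q[idx] = q_sorted[rank_i]
    return q


def chi2_oracle(table):
    """Pearson chi-square via sum((O-E)^2/E) over all cells; df=(r-1)(c-1)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def auc_oracle(scores, truth, positive="ABC"):
    """Concordance probability by exhaustive (positive, negative) pair counting."""
    pos = [s for s, t in zip(scores, truth) if t == positive]
    neg = [s for s, t in zip(scores, truth) if t != positive]
    concordant = 0.0
    for sp, sn in itertools.product(pos, neg):
        if sp > sn:
            concordant += 1.0
        elif sp == sn:
            concordant += 0.5
    return concordant / (len(pos) * len(neg))


def vote_oracle(weights, boundaries, expression, majority="GCB"):
    """Per-gene vote tabulation by explicit loop over genes."""
    v_abc = v_gcb = 0.0
    for w, b, e in zip(weights, boundaries, expression):
        magnitude = abs(w) * abs(e - b)
        direction = math.copysign(1.0, w) * (e - b)
        if direction > 0:
            v_abc += magnitude
        elif direction < 0:
            v_gcb += magnitude
    if v_abc > v_gcb:
        predicted = "ABC"
    elif v_abc < v_gcb:
        predicted = "GCB"
    else:
        predicted = majority
    return v_abc, v_gcb, predicted


def cox_neg_log_partial_likelihood(beta, times, events, x):
    """Negative log partial likelihood for one covariate (no ties assumed)."""
    order = np.argsort(times)
    times, events, x = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]
    nll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = times >= times[i]
        nll -= beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return nll


def cox_oracle(times, events, x):
    """Maximum-partial-likelihood log-HR by bounded 1-D search."""
    res = minimize_scalar(
        cox_neg_log_partial_likelihood,
        bounds=(-10, 10),
        args=(times, events, x),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def km_oracle(times, events):
    """Product-limit estimate at each distinct event time, by hand."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    s = 1.0
    curve = {}
    for t in sorted(set(times[events == 1])):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / at_risk
        curve[t] = s
    return curve
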