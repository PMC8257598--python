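"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (explicit loops, enumeration, grid
search) and shares no code with the package, so agreement is meaningful.
"""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_running_sum(genes, metric, members, weight_exp):
    """Step-by-step weighted KS running sum down an already-ranked list."""
    members = set(members)
    hit_weights = [abs(m) ** weight_exp for g, m in zip(genes, metric)
                   if g in members]
    total_hit = sum(hit_weights)
    n_miss = len(genes) - len(hit_weights)
    running = []
    s = 0.0
    for g, m in zip(genes, metric):
        if g in members:
            s += (abs(m) ** weight_exp) / total_hit
        else:
            s -= 1.0 / n_miss
        running.append(s)
    es = max(running, key=abs)
    return es, running


def brute_mad(values):
    values = sorted(values)
    med = _median(values)
    return _median(sorted(abs(v - med) for v in values))


def _median(sorted_vals):
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


def welch_t(x, y):
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    denom = math.sqrt(vx / nx + vy / ny)
    return 0.0 if denom == 0 else (mx - my) / denom


def exhaustive_perm_p(values, mask_high):
    """Plus-one permutation p of |Welch t| over all distinct relabelings."""
    values = list(values)
    n = len(values)
    n_high = sum(mask_high)
    obs = abs(welch_t([v for v, m in zip(values, mask_high) if m],
                      [v for v, m in zip(values, mask_high) if not m]))
    count = 0
    combos = list(combinations(range(n), n_high))
    for idx in combos:
        sel = set(idx)
        t = welch_t([values[i] for i in range(n) if i in sel],
                    [values[i] for i in range(n) if i not in sel])
        if abs(t) >= obs:
            count += 1
    return (1 + count) / (1 + len(combos))


def product_limit(times, events):
    """Kaplan-Meier survival at each distinct observed time (ascending)."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    times = [times[i] for i in order]
    events = [events[i] for i in order]
    distinct = sorted(set(times))
    s = 1.0
    out = []
    for t in distinct:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        if d:
            s *= 1.0 - d / at_risk
        out.append((t, s, at_risk))
    return out


def ranksum_exact_p(x, y):
    """Two-sided exact rank-sum p by enumeration of all group assignments."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    mean_w = nx * (n + 1) / 2.0
    count = total = 0
    for idx in combinations(range(n), nx):
        w = sum(ranks[pooled[i]] for i in idx)
        total += 1
        if abs(w - mean_w) >= abs(obs - mean_w) - 1e-12:
            count += 1
    return count / total


def fisher_minlike_p(a, b, c, d):
    """Two-sided Fisher p: sum of hypergeometric probs <= observed's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = hyper(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(hyper(k) for k in range(lo, hi + 1)
               if hyper(k) <= p_obs * (1 + 1e-9))


def cox_partial_loglik(beta, times, events, x):
    """Breslow log partial likelihood for a single covariate (no ties)."""
    ll = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if not ei:
            continue
        risk = [j for j in range(len(times)) if times[j] >= ti]
        denom = sum(math.exp(beta * x[j]) for j in risk)
        ll += beta * x[i] - math.log(denom)
    return ll


def cox_grid_mle(times, events, x, lo=-4.0, hi=4.0, steps=8001):
    grid = np.linspace(lo, hi, steps)
    lls = [cox_partial_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def logrank_chi2(times, events, groups):
    """Manual O-E log-rank chi-square for two groups (labels 0/1)."""
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    O = E = V = 0.0
    for t in distinct:
        at_risk = [i for i in range(len(times)) if times[i] >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if groups[i] == 1)
        d = sum(1 for i in range(len(times))
                if times[i] == t and events[i] == 1)
        d1 = sum(1 for i in range(len(times))
                 if times[i] == t and events[i] == 1 and groups[i] == 1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V
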