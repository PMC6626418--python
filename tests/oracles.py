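"""Independent reference implementations used only to check the package.

These are deliberately written as direct transcriptions of textbook
definitions (loops, enumeration, recursion) and share no code with the
package's implementations.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def km_oracle(times, events):
    """Direct product-limit estimate: returns (event_times, survival)."""
    times = list(map(float, times))
    events = list(map(int, events))
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    surv = []
    s = 1.0
    for t in distinct:
        n_at_risk = sum(1 for x in times if x >= t)
        n_events = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1.0 - n_events / n_at_risk
        surv.append(s)
    return distinct, surv


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from explicit 2x2 tables per event time."""
    times = list(times_a) + list(times_b)
    events = list(events_a) + list(events_b)
    group = [0] * len(times_a) + [1] * len(times_b)
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in distinct:
        at_risk = [i for i, x in enumerate(times) if x >= t]
        n = len(at_risk)
        n_a = sum(1 for i in at_risk if group[i] == 0)
        d = sum(1 for i, x in enumerate(times) if x == t and events[i] == 1)
        d_a = sum(
            1 for i, x in enumerate(times) if x == t and events[i] == 1 and group[i] == 0
        )
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def logrank_permutation_p(times_a, events_a, times_b, events_b):
    """Exact permutation p-value of the log-rank chi-square (small n only)."""
    times = list(times_a) + list(times_b)
    events = list(events_a) + list(events_b)
    n_a = len(times_a)
    observed = logrank_oracle(times_a, events_a, times_b, events_b)
    total = 0
    as_extreme = 0
    for idx_a in combinations(range(len(times)), n_a):
        set_a = set(idx_a)
        ta = [times[i] for i in idx_a]
        ea = [events[i] for i in idx_a]
        tb = [times[i] for i in range(len(times)) if i not in set_a]
        eb = [events[i] for i in range(len(times)) if i not in set_a]
        stat = logrank_oracle(ta, ea, tb, eb)
        total += 1
        if stat >= observed - 1e-12:
            as_extreme += 1
    return as_extreme / total


def fisher_exact_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration of a 2x2 table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = pmf(k)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def welzl_sphere(points):
    """Exact minimal enclosing sphere (Welzl's algorithm, 3-D)."""
    pts = [np.asarray(p, dtype=float) for p in points]

    def sphere_from(boundary):
        if not boundary:
            return np.zeros(3), 0.0
        if len(boundary) == 1:
            return boundary[0], 0.0
        if len(boundary) == 2:
            c = (boundary[0] + boundary[1]) / 2
            return c, float(np.linalg.norm(boundary[0] - c))
        # solve |x - p_i|^2 = r^2 for 3 or 4 boundary points
        p0 = boundary[0]
        rows = [2 * (p - p0) for p in boundary[1:]]
        rhs = [float(p @ p - p0 @ p0) for p in boundary[1:]]
        a = np.vstack(rows)
        if len(boundary) == 3:
            # constrain center to the plane of the 3 points
            normal = np.cross(boundary[1] - p0, boundary[2] - p0)
            a = np.vstack([a, normal])
            rhs.append(float(normal @ p0))
        center = np.linalg.lstsq(a, np.array(rhs), rcond=None)[0]
        return center, float(np.linalg.norm(boundary[0] - center))

    def contains(center, radius, p):
        return np.linalg.norm(p - center) <= radius + 1e-9

    def recurse(subset, boundary):
        if not subset or len(boundary) == 4:
            return sphere_from(boundary)
        p = subset[0]
        center, radius = recurse(subset[1:], boundary)
        if contains(center, radius, p):
            return center, radius
        return recurse(subset[1:], boundary + [p])

    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))
    return recurse([pts[i] for i in order], [])
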