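"""Independent brute-force oracles used to check the statistics wrappers.

These enumerate pairs / ECDF jump points directly and never call the code
paths they verify.
"""

from __future__ import annotations

import math

import numpy as np


def ks_statistic_bruteforce(a, b) -> float:
    """sup |ECDF_a - ECDF_b| evaluated over the pooled jump set."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = 0.0
    for t in np.unique(np.concatenate([a, b])):
        d = max(d, abs(np.mean(a <= t) - np.mean(b <= t)))
    return float(d)


def kendall_tau_b_bruteforce(a, b) -> float:
    """Tau-b from exhaustive enumeration of all n-choose-2 pairs."""
    a = list(a)
    b = list(b)
    n = len(a)
    concordant = discordant = ties_a = ties_b = ties_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_both += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif (da > 0) == (db > 0):
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - (ties_a + ties_both)) * (n0 - (ties_b + ties_both)))
    if denom == 0:
        return math.nan
    return (concordant - discordant) / denom


def mann_whitney_u_bruteforce(a, b) -> float:
    """U = #{a_i > b_j} + 0.5 * #{a_i = b_j} by exhaustive pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def buffered_rectangle_annulus_area(w: float, h: float, r: float) -> float:
    """Exact area of (rectangle buffered by r) minus the rectangle:
    2r(w+h) + pi r^2."""
    return 2.0 * r * (w + h) + math.pi * r * r


def montecarlo_union_area(geoms, bounds, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo estimate (value, SE) of the area of a union of shapely
    geometries by uniform sampling in ``bounds``."""
    import shapely

    minx, miny, maxx, maxy = bounds
    rng = np.random.default_rng(seed)
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = np.zeros(n, dtype=bool)
    for g in geoms:
        shapely.prepare(g)
        inside |= shapely.contains_xy(g, xs, ys)
    box_area = (maxx - minx) * (maxy - miny)
    p = inside.mean()
    return box_area * p, box_area * math.sqrt(p * (1 - p) / n)
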