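"""Naive reference implementations used to validate the pipeline's fast paths.

Everything here favours transparency over speed: full distance matrices,
explicit candidate enumeration, exact rational arithmetic.  These functions
are independent re-derivations of the corresponding contracts and are used as
oracles by the test suite and the acceptance script; they are not part of the
analysis pipeline itself.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def dbscan_reference(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Density-reachability DBSCAN from first principles.

    Builds the full eps-neighborhood graph, takes connected components of the
    core points (a core point has >= min_pts neighbors within eps, itself
    included), and attaches each border point to the earliest-created cluster
    (clusters are created in input order of their first core point) among
    those whose cores reach it.  Returns labels with -1 for noise.
    """
    n = len(xy)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    diff = xy[:, None, :] - xy[None, :, :]
    within = (diff ** 2).sum(axis=2) <= eps * eps
    neighbor_counts = within.sum(axis=1)  # self included
    core = neighbor_counts >= min_pts

    # connected components of the core-core graph
    component = np.full(n, -1, dtype=int)
    n_comp = 0
    for s in range(n):
        if not core[s] or component[s] != -1:
            continue
        stack = [s]
        component[s] = n_comp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(within[u] & core):
                if component[v] == -1:
                    component[v] = n_comp
                    stack.append(v)
        n_comp += 1

    # clusters are numbered by the input order of their first core point
    order = {}
    for i in range(n):
        if core[i] and component[i] not in order:
            order[component[i]] = len(order)
    for i in range(n):
        if core[i]:
            labels[i] = order[component[i]]
        else:
            reachable = [order[component[j]] for j in np.flatnonzero(within[i] & core)]
            if reachable:
                labels[i] = min(reachable)
    return labels


def find_microsatellites_reference(
    sequence: str, min_tract: int = 7, max_tract: int = 60, max_unit: int = 4
) -> list:
    """Enumerate every (start, period) candidate and resolve overlaps.

    Returns a list of ``(start, end, unit)`` tuples sorted by start; the unit
    is the lexicographically smallest rotation.  Mirrors the scanner contract:
    maximal perfect tracts, smallest fundamental period, tract length within
    bounds, overlaps resolved smallest-unit-first then longest-tract.
    """
    s = sequence.upper()
    n = len(s)

    def ok(i: int, p: int) -> bool:
        # a match commits s[i..i+p] to the tract; N anywhere in it breaks it
        return i + p < n and s[i] == s[i + p] and "N" not in s[i:i + p + 1]

    candidates = []
    for p in range(1, max_unit + 1):
        for a in range(n):
            if not ok(a, p):
                continue
            if a > 0 and ok(a - 1, p):
                continue  # not left-maximal
            b = a
            while ok(b, p):
                b += 1
            end = b + p  # tract [a, end)
            length = end - a
            if not min_tract <= length <= max_tract:
                continue
            tract = s[a:end]
            fundamental = min(
                q for q in range(1, length + 1)
                if all(tract[i] == tract[i + q] for i in range(length - q))
            )
            if fundamental != p:
                continue
            unit = sorted(s[a + i:a + p] + s[a:a + i] for i in range(p))[0]
            candidates.append((p, -(length), a, end, unit))

    candidates.sort()
    accepted = []
    for p, neg_len, a, end, unit in candidates:
        if all(end <= a2 or e2 <= a for a2, e2, _ in accepted):
            accepted.append((a, end, unit))
    return sorted(accepted)


def fisher_reference(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration over one margin.

    Probabilities are computed with exact rational arithmetic; a table counts
    as at-least-as-extreme when its probability is <= the observed one within
    a 1 + 1e-7 relative tolerance.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    if denom == 0:
        return 1.0
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if float(p_k) <= float(p_obs) * (1.0 + 1e-7):
            total += p_k
    return min(1.0, float(total))


def ks_d_reference(x, y) -> float:
    """Sup of |F_x(t) - F_y(t)| by direct counting at every observed value."""
    xs, ys = list(x), list(y)
    best = 0.0
    for t in set(xs) | set(ys):
        fx = sum(v <= t for v in xs) / len(xs)
        fy = sum(v <= t for v in ys) / len(ys)
        best = max(best, abs(fx - fy))
    return best


def ks_exact_permutation_p(x, y) -> float:
    """Exact permutation p-value for the two-sample KS statistic at tiny n.

    Enumerates every assignment of the pooled observations into groups of the
    original sizes and counts assignments with D at least as large as
    observed.  Only feasible for very small samples.
    """
    from itertools import combinations

    pooled = list(x) + list(y)
    m = len(x)
    d_obs = ks_d_reference(x, y)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if ks_d_reference(xs, ys) >= d_obs - 1e-12:
            count += 1
    return count / total
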