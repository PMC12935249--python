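"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code path with the
package: gift-wrapping hull + shoelace area, quadratic nearest-neighbour
scan, full enumeration of the rank-sum null, the Benjamini–Hochberg
step-up formula written out directly, and a hand-rolled Huber IRLS.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hull_area_bruteforce(points: np.ndarray) -> float:
    """Convex-hull area by gift wrapping + shoelace; collinear -> 0."""
    pts = [tuple(p) for p in np.asarray(points, dtype=float)]
    uniq = sorted(set(pts))
    if len(uniq) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = uniq[0]
    hull = [start]
    current = start
    while True:
        candidate = None
        for p in uniq:
            if p == current:
                continue
            if candidate is None:
                candidate = p
                continue
            c = cross(current, candidate, p)
            if c < 0 or (
                c == 0
                and (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
                > (candidate[0] - current[0]) ** 2 + (candidate[1] - current[1]) ** 2
            ):
                candidate = p
        hull.append(candidate)
        current = candidate
        if current == start:
            break
    area = 0.0
    for (x0, y0), (x1, y1) in zip(hull, hull[1:]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def nnd_bruteforce(points: np.ndarray) -> tuple[float, float]:
    """(mean, sample sd) of nearest-neighbour distances by double loop."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    nnd = []
    for i in range(n):
        best = math.inf
        for j in range(n):
            if i != j:
                d = math.dist(pts[i], pts[j])
                best = min(best, d)
        nnd.append(best)
    nnd = np.asarray(nnd)
    return float(nnd.mean()), float(nnd.std(ddof=1))


def ranksum_exact_p(a, b) -> float:
    """Two-sided rank-sum p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(a)
    ew = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - ew) >= abs(w_obs - ew) - 1e-12:
            count += 1
    return count / total


def bh_adjust(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up, written out from the definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def huber_irls(x, y, t: float = 1.345, iters: int = 200) -> tuple[float, float]:
    """Hand-rolled Huber M-estimate of (intercept, slope) with MAD scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(iters):
        resid = y - X @ beta
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            break
        u = resid / scale
        w = np.where(np.abs(u) <= t, 1.0, t / np.abs(u))
        W = np.diag(w)
        new = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return float(beta[0]), float(beta[1])


def pearson_by_hand(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def ellipse_polygon(centroid, cov, r2: float, k: int = 4096) -> np.ndarray:
    """Dense polygon approximation of a Mahalanobis ellipse boundary."""
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    L = np.linalg.cholesky(np.asarray(cov, dtype=float))
    return np.asarray(centroid) + math.sqrt(r2) * circle @ L.T
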