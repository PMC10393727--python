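"""Independent brute-force oracles for the diversity metrics.

Everything here is deliberately naive (explicit loops, shoelace areas,
Kruskal via networkx, Pruefer-sequence tree enumeration) and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def bf_centroid(points, weights=None):
    points = np.asarray(points, float)
    if weights is None:
        weights = np.ones(len(points))
    w = np.asarray(weights, float)
    c = np.zeros(points.shape[1])
    for p, wi in zip(points, w):
        c += wi * p
    return c / w.sum()


def bf_mean_dist_to(points, ref, weights=None):
    points = np.asarray(points, float)
    if weights is None:
        weights = np.ones(len(points))
    w = np.asarray(weights, float)
    tot = 0.0
    for p, wi in zip(points, w):
        tot += wi * math.dist(p, ref)
    return tot / w.sum()


def bf_extremization(points, all_points, norm, weights=None, all_weights=None):
    return bf_mean_dist_to(points, bf_centroid(all_points, all_weights), weights) / norm


def bf_dispersion(points, norm, weights=None):
    if len(points) == 1:
        return 0.0
    return bf_mean_dist_to(points, bf_centroid(points, weights), weights) / norm


def bf_originality(points, norm):
    points = np.asarray(points, float)
    total = 0.0
    for i in range(len(points)):
        best = min(math.dist(points[i], points[j])
                   for j in range(len(points)) if j != i)
        total += best
    return total / len(points) / norm


def bf_distance_between(points_a, points_b, norm, wa=None, wb=None):
    return math.dist(bf_centroid(points_a, wa), bf_centroid(points_b, wb)) / norm


def convex_hull_2d(points):
    """Monotone-chain hull; returns vertices in counter-clockwise order."""
    pts = sorted({(float(x), float(y)) for x, y in points})
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def shoelace_area(vertices):
    a = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        a += x1 * y2 - x2 * y1
    return abs(a) / 2.0


def bf_hull_area_2d(points):
    """Convex-hull area in d=2, or None when degenerate."""
    verts = convex_hull_2d(points)
    if len(verts) < 3:
        return None
    area = shoelace_area(verts)
    return area if area > 0 else None


def bf_mst_lengths(points):
    """MST branch lengths via networkx Kruskal (index-ordered tie-break)."""
    points = np.asarray(points, float)
    G = nx.Graph()
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            G.add_edge(i, j, weight=math.dist(points[i], points[j]))
    T = nx.minimum_spanning_tree(G, algorithm="kruskal")
    return sorted(d["weight"] for _, _, d in T.edges(data=True))


def bf_evenness(points):
    lengths = bf_mst_lengths(points)
    S = len(points)
    total = sum(lengths)
    if total == 0:
        return 1.0
    eq = 1.0 / (S - 1)
    acc = sum(min(l / total, eq) for l in lengths)
    return (acc - eq) / (1.0 - eq)


def exhaustive_mst_total(points):
    """Minimum total length over ALL spanning trees (Pruefer enumeration).

    Only feasible for n <= 7 (n**(n-2) trees).
    """
    points = np.asarray(points, float)
    n = len(points)
    best = math.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        T = nx.from_prufer_sequence(list(seq))
        total = sum(math.dist(points[u], points[v]) for u, v in T.edges)
        best = min(best, total)
    return best


def varimax_criterion_normalized(loadings):
    """Raw varimax criterion on Kaiser-normalized loadings (independent form)."""
    L = np.asarray(loadings, float)
    h = np.sqrt((L ** 2).sum(axis=1))
    L = L / h[:, None]
    val = 0.0
    p = L.shape[0]
    for col in L.T:
        sq = col ** 2
        val += (sq ** 2).sum() / p - (sq.sum() / p) ** 2
    return val


def rotate_2d(loadings, theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.asarray(loadings, float) @ np.array([[c, -s], [s, c]])
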