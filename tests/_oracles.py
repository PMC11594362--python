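"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they check: the silhouette
oracle enumerates all pairwise distances, the range oracle rasterizes the
convex hull of cell-corner points with dense point-in-polygon sampling,
and the Kruskal-Wallis oracle computes mid-ranks and the defining formula
directly.
"""

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import ConvexHull


def brute_force_silhouette(X, labels):
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            scores[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        scores[i] = (b - a) / max(a, b)
    return scores.mean()


def brute_force_range(cells, samples=60):
    corners = []
    for x, y in cells:
        corners += [(x, y), (x + 1, y), (x, y + 1), (x + 1, y + 1)]
    corners = np.array(sorted(set(corners)), dtype=float)
    hull = ConvexHull(corners)
    path = MplPath(corners[hull.vertices])
    xs, ys = corners[:, 0], corners[:, 1]
    count = 0
    for cx in range(int(xs.min()) - 1, int(xs.max()) + 1):
        for cy in range(int(ys.min()) - 1, int(ys.max()) + 1):
            gx, gy = np.meshgrid(
                np.linspace(cx + 1e-4, cx + 1 - 1e-4, samples),
                np.linspace(cy + 1e-4, cy + 1 - 1e-4, samples),
            )
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            if path.contains_points(pts).any():
                count += 1
    return float(count)


def hand_kruskal_h(groups):
    pooled = np.concatenate(groups)
    order = pooled.argsort(kind="stable")
    sorted_vals = pooled[order]
    r = np.arange(1, len(pooled) + 1, dtype=float)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i : j + 1] = r[i : j + 1].mean()
        i = j + 1
    ranks = np.empty_like(pooled, dtype=float)
    ranks[order] = r
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        rg = ranks[start : start + len(g)]
        h += rg.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie
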