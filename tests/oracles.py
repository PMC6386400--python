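"""Independent reference implementations used only to check the package.

Everything here is written from first principles (loops, brute force,
closed forms) and deliberately shares no code with restmvpa.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def rank_with_midranks(x):
    """Ranks of a 1-D array with mid-ranks for ties (1-based)."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def kendall_w(block):
    """Kendall's W straight from the rank definition."""
    block = np.asarray(block, float)
    K, T = block.shape
    ranks = np.array([rank_with_midranks(row) for row in block])
    R = ranks.sum(axis=0)
    Rbar = R.mean()
    S = sum((r - Rbar) ** 2 for r in R)
    return 12.0 * S / (K * K * (T**3 - T))


def pearson_r(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    den = np.sqrt(np.sum(a * a) * np.sum(b * b))
    return float(np.sum(a * b) / den) if den > 0 else 0.0


def degree_centrality_brute(series, r_threshold, weighted=True):
    """O(V^2) weighted degree of supra-threshold correlations."""
    V = series.shape[0]
    dc = np.zeros(V)
    for i in range(V):
        for j in range(V):
            if i == j:
                continue
            r = pearson_r(series[i], series[j])
            if r > r_threshold:
                dc[i] += r if weighted else 1.0
    return dc


def flood_fill_components(binary, connectivity=26):
    """BFS connected-component labelling of a 3-D boolean grid."""
    binary = np.asarray(binary, bool)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                dist = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and dist > 1) or \
                   (connectivity == 18 and dist > 2):
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(binary.shape, int)
    current = 0
    for start in zip(*np.nonzero(binary & (labels == 0))):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (0 <= nx < binary.shape[0] and 0 <= ny < binary.shape[1]
                        and 0 <= nz < binary.shape[2]
                        and binary[nx, ny, nz] and not labels[nx, ny, nz]):
                    labels[nx, ny, nz] = current
                    queue.append((nx, ny, nz))
    return labels, current


def soft_threshold(z, lam):
    return np.sign(z) * max(abs(z) - lam, 0.0)


def lasso_1d(x, u, lam):
    """Closed-form single-feature LASSO coefficient (centred inputs)."""
    x = np.asarray(x, float)
    u = np.asarray(u, float)
    n = len(x)
    xc = x - x.mean()
    uc = u - u.mean()
    return soft_threshold(float(xc @ uc) / n, lam) / (float(xc @ xc) / n)


def pooled_t(x0, x1):
    """Textbook pooled-variance two-sample t (group1 minus group0)."""
    x0 = np.asarray(x0, float)
    x1 = np.asarray(x1, float)
    n0, n1 = len(x0), len(x1)
    sp2 = (np.sum((x0 - x0.mean()) ** 2) + np.sum((x1 - x1.mean()) ** 2)) \
        / (n0 + n1 - 2)
    return (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))


def sphere_voxels(shape, center_mm, radius_mm, voxel_size):
    """Enumerate voxels whose centers lie within radius of a point (mm)."""
    hits = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                p = np.array([i, j, k]) * voxel_size
                if np.sum((p - np.asarray(center_mm)) ** 2) <= radius_mm**2 + 1e-9:
                    hits.append((i, j, k))
    return hits
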