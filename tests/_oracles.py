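"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: peak detection is an
exhaustive per-voxel neighbor scan, AUC is the O(n^2) pairwise count.
"""

import numpy as np


def brute_force_peaks(data, min_abs=0.0):
    """Exhaustive 26-neighbor scan: every finite voxel strictly greater
    (resp. smaller) than all finite neighbors, |amplitude| >= min_abs.
    Returns a set of (x, y, t) tuples."""
    nx, ny, nt = data.shape
    out = set()
    for x in range(nx):
        for y in range(ny):
            for t in range(nt):
                v = data[x, y, t]
                if not np.isfinite(v) or abs(v) < min_abs:
                    continue
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dt in (-1, 0, 1):
                            if dx == dy == dt == 0:
                                continue
                            xx, yy, tt = x + dx, y + dy, t + dt
                            if 0 <= xx < nx and 0 <= yy < ny and 0 <= tt < nt:
                                w = data[xx, yy, tt]
                                if np.isfinite(w):
                                    neigh.append(w)
                if not neigh:
                    continue
                if all(v > w for w in neigh) or all(v < w for w in neigh):
                    out.add((x, y, t))
    return out


def pairwise_auc(scores, labels, positive):
    """AUC as the probability that a random positive outranks a random
    negative, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == positive]
    neg = scores[np.asarray(labels) != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def anova_icc(values):
    """One-way ANOVA mean squares and the (MSb - MSw)/(MSb + (k-1) MSw)
    intraclass correlation, computed from first principles."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = x.mean()
    group_means = x.mean(axis=1)
    ss_between = k * ((group_means - grand) ** 2).sum()
    ss_within = ((x - group_means[:, None]) ** 2).sum()
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return msb, msw, (msb - msw) / (msb + (k - 1) * msw)
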