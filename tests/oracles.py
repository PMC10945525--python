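"""Naive reference implementations used only to check the package.

Everything here is written for clarity, not speed: explicit loops, textbook
formulas, brute-force enumeration.  These stay independent of the library
code paths they validate.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- morphology
def naive_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    """BFS labeling with 8-connectivity; drop components below min_size."""
    n, m = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    out = np.zeros_like(mask, dtype=bool)
    for si in range(n):
        for sj in range(m):
            if not mask[si, sj] or seen[si, sj]:
                continue
            comp = [(si, sj)]
            seen[si, sj] = True
            queue = [(si, sj)]
            while queue:
                i, j = queue.pop()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        a, b = i + di, j + dj
                        if 0 <= a < n and 0 <= b < m and mask[a, b] \
                                and not seen[a, b]:
                            seen[a, b] = True
                            comp.append((a, b))
                            queue.append((a, b))
            if len(comp) >= min_size:
                for i, j in comp:
                    out[i, j] = True
    return out


def _diamond_offsets(radius: int):
    return [(di, dj) for di in range(-radius, radius + 1)
            for dj in range(-radius, radius + 1)
            if abs(di) + abs(dj) <= radius]


def naive_diamond_close(mask: np.ndarray, radius: int,
                        circular: bool) -> np.ndarray:
    """Dilation then erosion by the definition, point by point.

    Off-matrix points count as background for the dilation and foreground
    for the erosion; on a circular map indices wrap instead.
    """
    if radius <= 0:
        return mask.astype(bool)
    n, m = mask.shape
    offs = _diamond_offsets(radius)

    def get(grid, i, j, outside):
        if circular:
            return grid[i % n, j % m]
        if 0 <= i < n and 0 <= j < m:
            return grid[i, j]
        return outside

    dil = np.zeros_like(mask, dtype=bool)
    for i in range(n):
        for j in range(m):
            dil[i, j] = any(get(mask, i + di, j + dj, False)
                            for di, dj in offs)
    out = np.zeros_like(mask, dtype=bool)
    for i in range(n):
        for j in range(m):
            out[i, j] = all(get(dil, i + di, j + dj, True)
                            for di, dj in offs)
    return out


def naive_width(mask: np.ndarray, circular: bool) -> np.ndarray:
    """Perpendicular diagonal run length at every bin, by enumeration."""
    n = mask.shape[0]
    width = np.zeros(n, dtype=int)
    for i in range(n):
        if not mask[i, i]:
            continue
        w = 1
        t = 1
        while True:
            a, b = i + t, i - t
            if circular:
                a, b = a % n, b % n
                if t > n // 2:
                    break
            elif a >= n or b < 0:
                break
            if mask[a, b]:
                w += 2
                t += 1
            else:
                break
        width[i] = w
    return width


# ---------------------------------------------------------------- statistics
def naive_median_mad(values) -> tuple[float, float]:
    v = sorted(float(x) for x in values)
    k = len(v)

    def med(xs):
        m = len(xs)
        return xs[m // 2] if m % 2 else 0.5 * (xs[m // 2 - 1] + xs[m // 2])

    m = med(v)
    return m, med(sorted(abs(x - m) for x in v))


def naive_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def naive_paired_t(x, y) -> tuple[float, int]:
    """Paired t statistic and df, textbook mean/SD-of-differences formula."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n), n - 1


# ---------------------------------------------------------------- balancing
def naive_scn(matrix: np.ndarray, sweeps: int = 10_000,
              tol: float = 1e-15) -> np.ndarray:
    """Alternating column-then-row L1 normalization to the fixed point.

    The opposite sweep order from the library; for symmetric input both
    orders converge to the same unique balanced form D.A.D up to a global
    scale.
    """
    m = matrix.astype(float).copy()
    for _ in range(sweeps):
        prev = m.copy()
        m = m / m.sum(axis=0)[None, :]
        m = m / m.sum(axis=1)[:, None]
        if np.max(np.abs(m - prev)) < tol:
            break
    m = 0.5 * (m + m.T)
    return m / m.sum(axis=1)[:, None].mean()


# ---------------------------------------------------------------- smoothing
def naive_gaussian_smooth(field: np.ndarray, sigma: float,
                          wrap: bool) -> np.ndarray:
    """Direct 2-D convolution with the truncated sampled Gaussian kernel
    (radius = round(4 * sigma), matching the library's smoother)."""
    r = int(round(4 * sigma))
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    n, m = field.shape
    out = np.zeros_like(field)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    a, b = i + di, j + dj
                    if wrap:
                        a, b = a % n, b % m
                    else:
                        a, b = min(max(a, 0), n - 1), min(max(b, 0), m - 1)
                    acc += kernel[di + r, dj + r] * field[a, b]
            out[i, j] = acc
    return out


def naive_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered circular moving average by direct summation (no NaNs)."""
    n = len(values)
    out = np.zeros(n)
    for i in range(n):
        # centered: for even windows the extra position falls on the right
        idx = [(i + d) % n for d in range(-((window - 1) // 2),
                                          window // 2 + 1)]
        out[i] = sum(values[j] for j in idx) / window
    return out
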