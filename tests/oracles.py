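"""Independent brute-force oracles used to cross-check the pipelines.

Everything here is deliberately naive (exhaustive search, explicit loops,
textbook formulas) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols:
                            if mask[nr, nc] and labels[nr, nc] == 0:
                                labels[nr, nc] = current
                                stack.append((nr, nc))
    return labels


def exhaustive_otsu(values: np.ndarray) -> float:
    """Single Otsu threshold by trying every distinct value as a cut point.

    Returns the cut maximizing between-class variance; foreground is
    ``value > threshold``.
    """
    v = np.asarray(values, dtype=float).ravel()
    candidates = np.unique(v)[:-1]
    best_t, best_var = candidates[0], -1.0
    for t in candidates:
        lo, hi = v[v <= t], v[v > t]
        w0, w1 = lo.size / v.size, hi.size / v.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def exhaustive_multi_otsu(values: np.ndarray, n_thresholds: int) -> tuple:
    """Multilevel Otsu by exhaustive search over distinct-value cut points."""
    import itertools

    v = np.asarray(values, dtype=float).ravel()
    candidates = np.unique(v)[:-1]
    best, best_var = None, -1.0
    for cuts in itertools.combinations(candidates, n_thresholds):
        edges = (-np.inf,) + cuts + (np.inf,)
        var = 0.0
        ok = True
        for lo, hi in zip(edges[:-1], edges[1:]):
            cls = v[(v > lo) & (v <= hi)]
            if cls.size == 0:
                ok = False
                break
            var += cls.size / v.size * (cls.mean() - v.mean()) ** 2
        if ok and var > best_var:
            best_var, best = var, cuts
    return best


def median_filter_naive(image: np.ndarray, size: int) -> np.ndarray:
    """Per-pixel sorted-neighborhood median with symmetric border padding."""
    half = size // 2
    padded = np.pad(image, half, mode="symmetric")
    out = np.empty_like(np.asarray(image, dtype=float))
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.median(padded[r: r + size, c: c + size])
    return out


def convolve_naive(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct correlation with symmetric padding (loops, no FFT)."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(np.asarray(image, dtype=float), (ph, pw), mode="symmetric")
    out = np.empty(image.shape, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = (padded[r: r + kh, c: c + kw] * kernel).sum()
    return out


def scan_peaks_naive(values: np.ndarray, min_height: float, min_separation: int):
    """Exhaustive peak scan: strict local maxima (endpoints allowed), greedy
    tallest-first separation enforcement."""
    v = np.asarray(values, dtype=float)
    n = v.size
    local = [
        i
        for i in range(n)
        if (i == 0 or v[i] > v[i - 1]) and (i == n - 1 or v[i] > v[i + 1]) and v[i] >= min_height
    ]
    kept: list[int] = []
    for i in sorted(local, key=lambda i: (-v[i], i)):
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
    return sorted(kept)


def rm_anova_naive(matrix: np.ndarray) -> tuple[float, float]:
    """Within-subject one-way ANOVA by fully expanded sums of squares."""
    from scipy import stats

    x = np.asarray(matrix, dtype=float)
    n, s = x.shape
    grand = x.mean()
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(s))
    ss_treat = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(s))
    ss_subj = sum(s * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = ss_total - ss_treat - ss_subj
    f = (ss_treat / (s - 1)) / (ss_err / ((s - 1) * (n - 1)))
    p = stats.f.sf(f, s - 1, (s - 1) * (n - 1))
    return f, p


def ks_sup_naive(values: np.ndarray) -> float:
    """sup |ECDF - plug-in normal CDF| evaluated at every ECDF jump point."""
    from scipy import stats

    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    cdf = stats.norm.cdf(v, loc=v.mean(), scale=v.std(ddof=1))
    d = 0.0
    for i in range(n):
        d = max(d, abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i]))
    return d
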