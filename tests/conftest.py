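"""Shared fixtures and independent oracles used across the suite.

The oracles here are deliberately naive (per-pixel loops, direct summation)
so they stay independent of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from nodulecad.otsu import Histogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-pixel sort-and-middle median with symmetric (reflect) padding."""
    p = window // 2
    padded = np.pad(image, p, mode="symmetric")
    out = np.empty_like(image)
    h, w = image.shape
    for r in range(h):
        for c in range(w):
            block = padded[r : r + window, c : c + window].ravel()
            out[r, c] = np.sort(block)[block.size // 2]
    return out


def naive_lbp_map(image: np.ndarray, m: int = 8, radius: float = 1.0) -> np.ndarray:
    """Per-pixel loop LBP oracle: bilinear sampling, angle 0 = east, CCW."""
    image = np.asarray(image, dtype=float)
    b = int(np.ceil(radius))
    h, w = image.shape
    theta = 2.0 * np.pi * np.arange(m) / m
    dc = radius * np.cos(theta)
    dr = -radius * np.sin(theta)
    for arr in (dr, dc):
        near = np.abs(arr - np.rint(arr)) < 1e-9
        arr[near] = np.rint(arr[near])
    out = np.zeros((h - 2 * b, w - 2 * b), dtype=np.int64)
    for r in range(b, h - b):
        for c in range(w - b - b):
            cc = c + b
            center = image[r, cc]
            code = 0
            for s in range(m):
                rs = r + dr[s]
                cs = cc + dc[s]
                if rs == int(rs) and cs == int(cs):
                    diff = image[int(rs), int(cs)] - center
                else:
                    # interpolate the difference so exact ties stay exact
                    r0, c0 = int(np.floor(rs)), int(np.floor(cs))
                    fr, fc = rs - r0, cs - c0
                    diff = (
                        (1 - fr) * (1 - fc) * (image[r0, c0] - center)
                        + (1 - fr) * fc * (image[r0, c0 + 1] - center)
                        + fr * (1 - fc) * (image[r0 + 1, c0] - center)
                        + fr * fc * (image[r0 + 1, c0 + 1] - center)
                    )
                if diff >= 0.0:
                    code |= 1 << s
            out[r - b, c] = code
    return out


def direct_class_stats(hist: Histogram, thresholds) -> tuple[list, list, float]:
    """Definition-level P_i, m_i, m_G by direct per-bin summation."""
    t = list(thresholds)
    bounds = [-1] + t + [hist.levels - 1]
    p = hist.probabilities
    P, M = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        gs = range(lo + 1, hi + 1)
        pi = sum(p[g] for g in gs)
        mi = sum(g * p[g] for g in gs) / pi if pi > 0 else 0.0
        P.append(pi)
        M.append(mi)
    m_g = sum(g * p[g] for g in range(hist.levels))
    return P, M, m_g


def direct_between_class_variance(hist: Histogram, thresholds) -> float:
    P, M, m_g = direct_class_stats(hist, thresholds)
    return sum(pi * (mi - m_g) ** 2 for pi, mi in zip(P, M))


def direct_within_class_variance(hist: Histogram, thresholds) -> float:
    """Pooled within-class variance, computed independently of sigma_B."""
    t = list(thresholds)
    bounds = [-1] + t + [hist.levels - 1]
    p = hist.probabilities
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        gs = list(range(lo + 1, hi + 1))
        pi = sum(p[g] for g in gs)
        if pi <= 0:
            continue
        mi = sum(g * p[g] for g in gs) / pi
        total += sum(p[g] * (g - mi) ** 2 for g in gs)
    return total


def random_histogram(rng, levels: int = 256, n_pixels: int = 4096) -> Histogram:
    """A rough random histogram (sparse support, uneven mass)."""
    n_bins = int(rng.integers(2, 12))
    support = rng.choice(levels, size=n_bins, replace=False)
    weights = rng.random(n_bins)
    weights /= weights.sum()
    counts = np.zeros(levels, dtype=np.int64)
    for s, w in zip(support, weights):
        counts[s] = max(1, int(round(w * n_pixels)))
    return Histogram.from_counts(counts)
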