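"""Gray-level histograms and the multilevel Otsu objective.

A threshold set x1 < ... < xk splits the gray range [0, L-1] into k+1
classes, class i covering the half-open interval (x_{i-1}, x_i] with
x0 = -1 and x_{k+1} = L-1.  With class probabilities P_i, class-conditional
means m_i and global mean m_G, the between-class variance is

    sigma_B^2 = sum_i P_i * (m_i - m_G)^2

and the optimization objective is equivalently the ratio tau =
sigma_B^2 / sigma_G^2 in [0, 1], where sigma_G^2 is the (probability
weighted) global variance.  Maximizing sigma_B^2 over threshold sets is the
multilevel Otsu criterion; by the law of total variance it is the same as
minimizing the pooled within-class variance.

``exhaustive_otsu`` enumerates every threshold combination (k <= 3) and is
the package's ground-truth oracle for the metaheuristic searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "ThresholdSet",
    "OtsuStatistics",
    "ConstantImageError",
    "compute_histogram",
    "between_class_variance",
    "global_variance",
    "tau",
    "otsu_statistics",
    "exhaustive_otsu",
    "make_objective",
]


class ConstantImageError(ValueError):
    """The Otsu objective is undefined on a constant image (sigma_G^2 = 0)."""


@dataclass(frozen=True)
class Histogram:
    """Per-gray-level pixel counts with derived probabilities."""

    counts: np.ndarray  # shape (L,), int64
    levels: int
    total: int
    probabilities: np.ndarray  # counts / total

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "Histogram":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total <= 0:
            raise ValueError("histogram must contain at least one pixel")
        return cls(
            counts=counts,
            levels=len(counts),
            total=total,
            probabilities=counts / total,
        )


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing cut points, each in [0, L-2]."""

    thresholds: tuple[int, ...]
    levels: int = 256

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) == 0:
            raise ValueError("at least one threshold required")
        if any(not (0 <= v <= self.levels - 2) for v in t):
            raise ValueError(f"thresholds must lie in [0, {self.levels - 2}]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class OtsuStatistics:
    """Class decomposition of a histogram under one threshold set."""

    class_probabilities: np.ndarray
    class_means: np.ndarray
    global_mean: float
    between_class_variance: float
    global_variance: float
    tau: float


def compute_histogram(image: np.ndarray, levels: int = 256) -> Histogram:
    """Tally pixel intensities into L bins."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(image.ravel().astype(np.int64), minlength=levels)
    if len(counts) > levels:
        raise ValueError("image contains intensities outside [0, levels-1]")
    return Histogram.from_counts(counts)


def _as_threshold_array(t, levels: int) -> np.ndarray:
    if isinstance(t, ThresholdSet):
        if t.levels != levels:
            raise ValueError("threshold set built for a different level count")
        return np.asarray(t.thresholds, dtype=np.int64)
    arr = np.asarray(t, dtype=np.int64)
    ThresholdSet(tuple(int(v) for v in arr), levels)  # validate
    return arr


def _class_stats(hist: Histogram, t: np.ndarray):
    """P_i, m_i for classes (x_{i-1}, x_i]; empty classes get m_i = 0."""
    p = hist.probabilities
    cum_p = np.cumsum(p)
    cum_gp = np.cumsum(np.arange(hist.levels) * p)
    bounds = np.concatenate(([-1], t, [hist.levels - 1]))
    hi = bounds[1:]
    lo = bounds[:-1]
    P = cum_p[hi] - np.where(lo >= 0, cum_p[np.maximum(lo, 0)], 0.0)
    S = cum_gp[hi] - np.where(lo >= 0, cum_gp[np.maximum(lo, 0)], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(P > 0, S / np.maximum(P, 1e-300), 0.0)
    return P, m


def between_class_variance(hist: Histogram, t) -> float:
    """sigma_B^2 = sum_i P_i (m_i - m_G)^2; empty classes contribute 0."""
    t = _as_threshold_array(t, hist.levels)
    P, m = _class_stats(hist, t)
    m_g = float(np.sum(np.arange(hist.levels) * hist.probabilities))
    return float(np.sum(P * (m - m_g) ** 2))


def global_variance(hist: Histogram) -> float:
    """sigma_G^2 = sum_g p_g (g - m_G)^2; zero iff one nonzero bin."""
    g = np.arange(hist.levels)
    p = hist.probabilities
    m_g = float(np.sum(g * p))
    return float(np.sum(p * (g - m_g) ** 2))


def tau(hist: Histogram, t) -> float:
    """tau = sigma_B^2 / sigma_G^2, the normalized Otsu objective in [0, 1]."""
    sg = global_variance(hist)
    if sg <= 0.0:
        raise ConstantImageError("tau undefined: constant image (sigma_G^2 = 0)")
    return between_class_variance(hist, t) / sg


def otsu_statistics(hist: Histogram, t) -> OtsuStatistics:
    """Full class decomposition for one threshold set."""
    ta = _as_threshold_array(t, hist.levels)
    P, m = _class_stats(hist, ta)
    g = np.arange(hist.levels)
    m_g = float(np.sum(g * hist.probabilities))
    sb = float(np.sum(P * (m - m_g) ** 2))
    sg = global_variance(hist)
    if sg <= 0.0:
        raise ConstantImageError("constant image (sigma_G^2 = 0)")
    return OtsuStatistics(
        class_probabilities=P,
        class_means=m,
        global_mean=m_g,
        between_class_variance=sb,
        global_variance=sg,
        tau=sb / sg,
    )


class OtsuObjective:
    """Fast sigma_B^2 evaluator over threshold vectors, with batch support.

    Precomputes cumulative probability and first-moment arrays so one
    evaluation is O(k).  ``batch`` evaluates an (n, k) array of candidate
    threshold vectors in one vectorized pass; optimizers use it to keep the
    per-candidate cost small.
    """

    def __init__(self, hist: Histogram):
        if global_variance(hist) <= 0.0:
            raise ConstantImageError(
                "Otsu objective undefined: constant image (sigma_G^2 = 0)"
            )
        self.hist = hist
        self.levels = hist.levels
        p = hist.probabilities
        g = np.arange(hist.levels)
        self._cum_p = np.concatenate(([0.0], np.cumsum(p)))  # index shifted by +1
        self._cum_gp = np.concatenate(([0.0], np.cumsum(g * p)))
        self.global_mean = float(self._cum_gp[-1])
        self.global_var = global_variance(hist)

    def __call__(self, t: np.ndarray) -> float:
        return float(self.batch(np.asarray(t, dtype=np.int64)[None, :])[0])

    def batch(self, T: np.ndarray) -> np.ndarray:
        """sigma_B^2 for each row of an (n, k) integer threshold array."""
        T = np.asarray(T, dtype=np.int64)
        n, k = T.shape
        bounds = np.empty((n, k + 2), dtype=np.int64)
        bounds[:, 0] = 0
        bounds[:, 1:-1] = T + 1  # +1: cum arrays are shifted
        bounds[:, -1] = self.levels
        P = self._cum_p[bounds[:, 1:]] - self._cum_p[bounds[:, :-1]]
        S = self._cum_gp[bounds[:, 1:]] - self._cum_gp[bounds[:, :-1]]
        m = np.divide(S, P, out=np.zeros_like(S), where=P > 0)
        return np.sum(P * (m - self.global_mean) ** 2, axis=1)


def make_objective(hist: Histogram) -> OtsuObjective:
    """Objective factory used by the optimizers (raises on constant images)."""
    return OtsuObjective(hist)


_MAX_ENUM = 3


def exhaustive_otsu(hist: Histogram, k: int) -> tuple[ThresholdSet, float]:
    """Globally optimal thresholds by full enumeration (oracle; k in 1..3).

    Ties are broken toward the lexicographically smallest threshold set:
    candidates are scanned in lexicographic order and only a strictly larger
    sigma_B^2 replaces the incumbent.
    """
    if not 1 <= k <= _MAX_ENUM:
        raise ValueError(f"exhaustive search supports k in 1..{_MAX_ENUM}")
    obj = make_objective(hist)
    L = hist.levels
    best_t: tuple[int, ...] | None = None
    best_f = -np.inf
    if k == 1:
        f = obj.batch(np.arange(L - 1, dtype=np.int64)[:, None])
        i = int(np.argmax(f))  # argmax returns the first (smallest) maximizer
        best_t, best_f = (i,), float(f[i])
    elif k == 2:
        for t1 in range(L - 2):
            t2 = np.arange(t1 + 1, L - 1, dtype=np.int64)
            T = np.column_stack([np.full_like(t2, t1), t2])
            f = obj.batch(T)
            i = int(np.argmax(f))
            if f[i] > best_f:
                best_f = float(f[i])
                best_t = (t1, int(t2[i]))
    else:
        for t1 in range(L - 3):
            for t2 in range(t1 + 1, L - 2):
                t3 = np.arange(t2 + 1, L - 1, dtype=np.int64)
                T = np.column_stack(
                    [np.full_like(t3, t1), np.full_like(t3, t2), t3]
                )
                f = obj.batch(T)
                i = int(np.argmax(f))
                if f[i] > best_f:
                    best_f = float(f[i])
                    best_t = (t1, t2, int(t3[i]))
    assert best_t is not None
    return ThresholdSet(best_t, L), best_f


def histogram_to_csv(hist: Histogram, path) -> None:
    """Dump per-level counts for debugging."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gray_level", "count", "probability"])
        for g in range(hist.levels):
            w.writerow([g, int(hist.counts[g]), float(hist.probabilities[g])])
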