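"""Local binary pattern (LBP) texture features.

The LBP code of a pixel compares m neighbors sampled on a circle of radius
R against the center value P_c:

    code = sum_{s=0}^{m-1} 1[P_s >= P_c] * 2^s

(the indicator is 1 when the difference P_s - P_c is >= 0, so a neighbor
equal to the center sets its bit).  Neighbor s sits at angle 2*pi*s/m,
angle 0 pointing east, proceeding counterclockwise; non-integer sampling
positions are bilinearly interpolated.  Codes depend only on intensity
differences, so they are invariant to a global gray-level shift.

A texture descriptor for an ROI is the normalized histogram of its code
map: either all 2^m raw-code bins, or "uniform" binning in which codes with
at most two circular 0<->1 transitions are binned by their number of set
bits (m+1 bins) and all remaining codes share one bin (m+2 bins total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LBPConfig",
    "FeatureVector",
    "lbp_code",
    "lbp_map",
    "lbp_features",
    "is_uniform",
    "uniform_bin_index",
]


@dataclass(frozen=True)
class LBPConfig:
    """Sampling geometry and binning for the LBP operator.

    neighbors
        m, the number of circular samples (default 8).
    radius
        R > 0, the sampling radius in pixels (default 1).
    uniform
        When True, histograms use the m+2 uniform-pattern bins.
    """

    neighbors: int = 8
    radius: float = 1.0
    uniform: bool = False

    def __post_init__(self) -> None:
        if self.neighbors < 4:
            raise ValueError("need at least 4 neighbors")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def n_bins(self) -> int:
        return self.neighbors + 2 if self.uniform else 2**self.neighbors


@dataclass
class FeatureVector:
    """Normalized LBP-code histogram for one ROI."""

    histogram: np.ndarray
    roi_id: int | None = None


def lbp_code(center: float, neighbors: np.ndarray) -> int:
    """Code for one pixel from its m neighbor values (bit s = neighbor s)."""
    neighbors = np.asarray(neighbors, dtype=float)
    bits = (neighbors - float(center)) >= 0.0
    return int(np.sum(bits * (1 << np.arange(len(neighbors)))))


def _offsets(config: LBPConfig) -> tuple[np.ndarray, np.ndarray]:
    """(drow, dcol) of each sample; angle 0 = east, counterclockwise.

    Counterclockwise in display coordinates means decreasing row for
    positive sine.  Offsets within 1e-9 of an integer are snapped so that
    integer positions are read exactly rather than interpolated.
    """
    s = np.arange(config.neighbors)
    theta = 2.0 * np.pi * s / config.neighbors
    dc = config.radius * np.cos(theta)
    dr = -config.radius * np.sin(theta)
    for arr in (dr, dc):
        near = np.abs(arr - np.rint(arr)) < 1e-9
        arr[near] = np.rint(arr[near])
    return dr, dc


def _bilinear_diff(
    img: np.ndarray, r: np.ndarray, c: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Bilinearly interpolated (sample - center) difference.

    Interpolating the differences rather than the raw intensities makes
    exact ties exact: when all four corners equal the center every term is
    zero and the comparison t >= 0 cannot be flipped by rounding.
    """
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    dr = r - r0
    dc = c - c0
    r1 = np.clip(r0 + 1, 0, img.shape[0] - 1)
    c1 = np.clip(c0 + 1, 0, img.shape[1] - 1)
    return (
        (1 - dr) * (1 - dc) * (img[r0, c0] - center)
        + (1 - dr) * dc * (img[r0, c1] - center)
        + dr * (1 - dc) * (img[r1, c0] - center)
        + dr * dc * (img[r1, c1] - center)
    )


def lbp_map(image: np.ndarray, config: LBPConfig | None = None) -> np.ndarray:
    """Per-pixel LBP codes for the interior (border of width ceil(R) cut).

    Returns an array of shape (H - 2*b, W - 2*b) with b = ceil(R), dtype
    int64, values in [0, 2^m - 1].
    """
    config = config or LBPConfig()
    image = np.asarray(image, dtype=float)
    b = int(np.ceil(config.radius))
    h, w = image.shape
    if h <= 2 * b + 1 or w <= 2 * b + 1:
        raise ValueError("image too small for the requested radius")
    dr_all, dc_all = _offsets(config)
    rows = np.arange(b, h - b)
    cols = np.arange(b, w - b)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    center = image[rr, cc]
    codes = np.zeros(center.shape, dtype=np.int64)
    for s in range(config.neighbors):
        dr, dc = dr_all[s], dc_all[s]
        if dr == int(dr) and dc == int(dc):
            diff = image[rr + int(dr), cc + int(dc)] - center
        else:
            diff = _bilinear_diff(image, rr + dr, cc + dc, center)
        codes |= (diff >= 0.0).astype(np.int64) << s
    return codes


def is_uniform(code: int, m: int) -> bool:
    """True when the circular bit pattern has at most two 0<->1 transitions."""
    bits = [(code >> s) & 1 for s in range(m)]
    transitions = sum(bits[s] != bits[(s + 1) % m] for s in range(m))
    return transitions <= 2


def uniform_bin_index(code: int, m: int) -> int:
    """Bin: popcount for uniform codes (0..m), m+1 for non-uniform ones."""
    if is_uniform(code, m):
        return bin(code).count("1")
    return m + 1


def _uniform_lut(m: int) -> np.ndarray:
    lut = np.empty(2**m, dtype=np.int64)
    for code in range(2**m):
        lut[code] = uniform_bin_index(code, m)
    return lut


def lbp_features(
    patch: np.ndarray, config: LBPConfig | None = None, roi_id: int | None = None
) -> FeatureVector:
    """Normalized code histogram of a patch (single cell, no spatial grid).

    Accepts either a 2-D grayscale array or a ``NoduleROI`` (its ``patch``
    is used).
    """
    config = config or LBPConfig()
    if hasattr(patch, "patch"):
        patch = patch.patch
    codes = lbp_map(patch, config)
    if config.uniform:
        codes = _uniform_lut(config.neighbors)[codes]
        counts = np.bincount(codes.ravel(), minlength=config.neighbors + 2)
    else:
        counts = np.bincount(codes.ravel(), minlength=2**config.neighbors)
    hist = counts / counts.sum()
    return FeatureVector(histogram=hist, roi_id=roi_id)


def rotate_code_map(codes: np.ndarray, quarter_turns: int, m: int = 8) -> np.ndarray:
    """Code map of the 90-degree-rotated source, from the original map.

    Rotating the image a quarter turn counterclockwise rotates the code map
    spatially and advances every neighbor index by m/4, i.e. bit-rolls each
    code.  Requires m divisible by 4.  Used for loss-free training-data
    augmentation.
    """
    if m % 4:
        raise ValueError("m must be divisible by 4 for quarter-turn rotation")
    q = quarter_turns % 4
    roll = (m // 4) * q
    mask = (1 << m) - 1
    out = np.rot90(codes, q)
    return ((out << roll) | (out >> (m - roll))) & mask if roll else out.copy()


def flip_code_map(codes: np.ndarray, m: int = 8) -> np.ndarray:
    """Code map of the left-right-mirrored source (bit permutation s -> m/2 - s)."""
    if m % 2:
        raise ValueError("m must be even for mirroring")
    flipped = np.fliplr(codes)
    out = np.zeros_like(flipped)
    for s in range(m):
        p = (m // 2 - s) % m
        out |= ((flipped >> p) & 1) << s
    return out


def feature_matrix(patches: list[np.ndarray], config: LBPConfig | None = None):
    """Stack per-patch histograms into an (n, n_bins) matrix."""
    config = config or LBPConfig()
    return np.vstack([lbp_features(p, config).histogram for p in patches])
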