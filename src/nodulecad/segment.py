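"""Threshold application and candidate-nodule ROI extraction.

``apply_thresholds`` maps each pixel to the index of the gray-level class it
falls in (class i covers (x_{i-1}, x_i]).  ``extract_rois`` takes the
candidate-lesion class — by default the brightest, since nodules are
hyperdense against the lung field — applies one 3x3 binary opening to
detach thin vessel-like structures, labels 8-connected components, filters
them by area, and returns them largest-first, each with a tight bounding
box, centroid and a fixed-size grayscale patch for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology, transform

from .otsu import ThresholdSet

__all__ = ["NoduleROI", "apply_thresholds", "extract_rois", "class_proportions"]


@dataclass
class NoduleROI:
    """One connected candidate-lesion component."""

    mask: np.ndarray  # full-size binary mask of this component
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area: int
    centroid: tuple[float, float]
    patch: np.ndarray  # grayscale crop resized to (patch_size, patch_size) uint8


def _thresholds_tuple(t) -> tuple[int, ...]:
    if isinstance(t, ThresholdSet):
        return t.thresholds
    return tuple(int(v) for v in t)


def apply_thresholds(image: np.ndarray, t) -> np.ndarray:
    """Per-pixel class index in 0..k by interval membership (x_{i-1}, x_i]."""
    cuts = np.asarray(_thresholds_tuple(t), dtype=np.int64)
    # first index i with cuts[i] >= g  ==  number of cuts strictly below g
    return np.searchsorted(cuts, np.asarray(image), side="left").astype(np.int64)


def class_proportions(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Fraction of pixels per class; sums to 1."""
    counts = np.bincount(labels.ravel(), minlength=n_classes)
    return counts / labels.size


def extract_rois(
    labels: np.ndarray,
    source: np.ndarray,
    min_area: int = 30,
    max_area: int | None = None,
    lesion_class: int | None = None,
    patch_size: int = 32,
    patch_margin: float = 0.25,
    opening: bool = True,
) -> list[NoduleROI]:
    """Connected candidate-lesion components, filtered by area, largest first.

    ``lesion_class`` defaults to the brightest class (``labels.max()``);
    ``max_area`` defaults to 20% of the image.  An empty list means "no
    lesion found" and is a valid outcome.  The patch is the source crop of
    the bounding box grown by ``patch_margin`` on each side, resized to
    ``patch_size`` with intensities preserved.
    """
    labels = np.asarray(labels)
    source = np.asarray(source)
    if labels.shape != source.shape:
        raise ValueError("labels and source must be aligned")
    if max_area is None:
        max_area = int(0.2 * labels.size)
    if lesion_class is None:
        lesion_class = int(labels.max())
    binary = labels == lesion_class
    if opening:
        binary = morphology.opening(binary, footprint=np.ones((3, 3), bool)).astype(bool)
    comp = measure.label(binary, connectivity=2)
    rois: list[NoduleROI] = []
    for region in measure.regionprops(comp):
        if not min_area <= region.area <= max_area:
            continue
        r0, c0, r1, c1 = region.bbox
        mask = comp == region.label
        # grow the crop so boundary texture is inside the patch
        mr = int(round((r1 - r0) * patch_margin))
        mc = int(round((c1 - c0) * patch_margin))
        rr0 = max(r0 - mr, 0)
        cc0 = max(c0 - mc, 0)
        rr1 = min(r1 + mr, labels.shape[0])
        cc1 = min(c1 + mc, labels.shape[1])
        crop = source[rr0:rr1, cc0:cc1].astype(float)
        # no anti-aliasing: the boundary texture that separates spiculated
        # from smooth nodules lives in the sharp intensity steps
        patch = transform.resize(
            crop, (patch_size, patch_size), preserve_range=True, anti_aliasing=False
        )
        rois.append(
            NoduleROI(
                mask=mask,
                bounding_box=(r0, c0, r1, c1),
                area=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                patch=np.clip(np.rint(patch), 0, 255).astype(np.uint8),
            )
        )
    rois.sort(key=lambda r: -r.area)
    return rois


def roi_union_mask(rois: list[NoduleROI], shape: tuple[int, int]) -> np.ndarray:
    """Union of component masks (all-zero when no ROI survived)."""
    out = np.zeros(shape, bool)
    for r in rois:
        out |= r.mask
    return out
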