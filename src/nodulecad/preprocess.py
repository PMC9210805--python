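"""Salt-and-pepper noise suppression by median filtering.

The filter replaces each pixel by the sample median of its square
neighborhood, g = median{x1, ..., xn}.  The sample median is also the
minimizer of the L1 objective M(g) = sum_k |x_k - g|, which is the property
that makes it robust to impulse (salt-and-pepper) noise: a single corrupted
value in the window cannot drag the median.

The window always covers a full (window x window) neighborhood: borders are
handled by padding (reflect or replicate), so the median is always taken
over an odd number of samples and no tie rule is ever exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MedianFilterConfig", "median_filter"]

_BORDER_TO_SCIPY = {"reflect": "reflect", "replicate": "nearest"}


@dataclass(frozen=True)
class MedianFilterConfig:
    """Square-window median filter settings.

    window
        Odd side length of the neighborhood (default 3, i.e. 9 samples).
    border_mode
        ``reflect`` mirrors edge pixels (default; avoids halos), ``replicate``
        repeats the edge pixel.
    """

    window: int = 3
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.border_mode not in _BORDER_TO_SCIPY:
            raise ValueError(f"border_mode must be one of {sorted(_BORDER_TO_SCIPY)}")


def median_filter(
    image: np.ndarray, config: MedianFilterConfig | None = None
) -> np.ndarray:
    """Median-filter an 8-bit grayscale image.

    Output has the same shape and dtype; every output intensity is one of the
    input intensities (the median never invents gray levels).
    """
    config = config or MedianFilterConfig()
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if config.window > min(image.shape):
        raise ValueError("window larger than the image")
    return ndimage.median_filter(
        image, size=config.window, mode=_BORDER_TO_SCIPY[config.border_mode]
    )
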