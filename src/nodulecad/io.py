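"""Reading and writing 8-bit grayscale slices (PNG/TIFF, single-slice DICOM)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_image"]


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros(arr.shape, np.uint8)
    return np.clip(np.rint((arr - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale slice as uint8; DICOM is window-rescaled to 8 bit."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        return _to_uint8(ds.pixel_array.astype(float))
    import imageio.v3 as iio

    return _to_uint8(iio.imread(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))
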