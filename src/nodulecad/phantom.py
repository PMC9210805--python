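"""Synthetic chest-CT phantom slices with ground-truth nodule masks.

The generator emulates a single axial chest-CT slice at 8-bit depth: a bright
body ellipse on a dark background, two dark lung fields, a few vessel-like
bright streaks inside the lungs, and zero or more bright nodules.  Benign
nodules are smooth ellipses; malignant nodules carry a spiculated boundary,
a circle whose radius is modulated by a small sum of sinusoids

    r(theta) = r0 * (1 + a * sum_j sin(k_j * theta + phi_j))

with 6-10 random spikes, so the two classes differ in boundary texture as
well as shape.  Salt-and-pepper noise (pixels forced to 0 or L-1 with equal
probability, chosen without replacement) is added at a configurable density.

Everything is deterministic for a fixed seed.  Coordinates are (row, col),
0-based, origin at the top-left; ranges are half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "generate_dataset",
    "save_phantom",
    "MALIGNANT",
    "BENIGN",
    "NONE",
]

MALIGNANT = "MALIGNANT"
BENIGN = "BENIGN"
NONE = "NONE"


class PlacementError(RuntimeError):
    """Raised when a nodule cannot be placed inside a lung field."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Intensities are gray levels in [0, levels-1]; ``noise_density`` is the
    fraction of pixels corrupted by salt-and-pepper noise.  ``malignant``
    holds one flag per nodule (spiculation on/off); it is broadcast when a
    single flag is given for several nodules.
    """

    image_size: tuple[int, int] = (256, 256)
    levels: int = 256
    nodule_count: int = 1
    nodule_radius_range: tuple[float, float] = (8.0, 14.0)
    malignant: tuple[bool, ...] = (False,)
    spiculation_amplitude: float = 0.3
    spike_count_range: tuple[int, int] = (6, 10)
    background_intensity: int = 10
    lung_intensity: int = 70
    body_intensity: int = 175
    vessel_intensity: int = 150
    nodule_intensity: int = 240
    noise_density: float = 0.05
    vessel_count: int = 6
    texture_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image must be at least 8x8")
        if not 0.0 <= self.noise_density <= 0.5:
            raise ValueError("noise_density must be in [0, 0.5]")
        if self.nodule_intensity <= self.lung_intensity:
            raise ValueError("nodules must be brighter than the lung field")
        if self.nodule_count < 0 or self.vessel_count < 0:
            raise ValueError("counts must be non-negative")
        flags = self.malignant
        if len(flags) == 1 and self.nodule_count > 1:
            flags = flags * self.nodule_count
        if self.nodule_count and len(flags) != self.nodule_count:
            raise ValueError("need one malignancy flag per nodule")
        object.__setattr__(self, "malignant", tuple(flags[: max(self.nodule_count, 1)]))

    @property
    def label(self) -> str:
        if self.nodule_count == 0:
            return NONE
        return MALIGNANT if any(self.malignant[: self.nodule_count]) else BENIGN


@dataclass
class GroundTruth:
    """Per-slice truth: nodule mask, class label and nodule geometry."""

    nodule_mask: np.ndarray
    label: str
    nodule_centers: list[tuple[float, float]] = field(default_factory=list)
    nodule_radii: list[float] = field(default_factory=list)


def _ellipse_mask(shape, center, semi_axes):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    ar, ac = semi_axes
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _benign_mask(shape, center, r0, rng):
    """Smooth nodule: ellipse with mild random eccentricity and orientation."""
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    dr = rr - center[0]
    dc = cc - center[1]
    ecc = rng.uniform(0.75, 1.0)
    ang = rng.uniform(0.0, np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / r0) ** 2 + (v / (r0 * ecc)) ** 2 <= 1.0


def _spiculated_boundary(center, r0, amplitude, spikes, rng, shape):
    """Polygon-free spiculated mask via angular radius modulation."""
    n_spikes = int(rng.integers(spikes[0], spikes[1] + 1))
    freqs = rng.integers(3, 9, size=n_spikes)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_spikes)
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    dr = rr - center[0]
    dc = cc - center[1]
    theta = np.arctan2(dc, dr)
    mod = np.zeros(np.broadcast(dr, dc).shape)
    for f, phi in zip(freqs, phases):
        mod += np.sin(f * theta + phi)
    mod = amplitude * mod / max(np.abs(mod).max(), 1e-12)
    radius = r0 * (1.0 + mod)
    return dr * dr + dc * dc <= radius * radius


def _lung_geometry(spec: PhantomSpec):
    h, w = spec.image_size
    body_c = (h * 0.52, w * 0.5)
    body_ax = (h * 0.40, w * 0.36)
    lung_dx = w * 0.175
    lung_c_left = (h * 0.52, w * 0.5 - lung_dx)
    lung_c_right = (h * 0.52, w * 0.5 + lung_dx)
    lung_ax = (h * 0.26, w * 0.115)
    return body_c, body_ax, (lung_c_left, lung_c_right), lung_ax


def _place_nodule(lungs, lung_ax, margin, rng, tries=200):
    """Sample a nodule center whose full extent fits inside one lung field."""
    for _ in range(tries):
        (cr, cc) = lungs[int(rng.integers(0, 2))]
        ar, ac = lung_ax
        u = rng.uniform(-1.0, 1.0)
        v = rng.uniform(-1.0, 1.0)
        if u * u + v * v > 1.0:
            continue
        r = cr + u * ar
        c = cc + v * ac
        # shrunken-ellipse test: nodule of extent `margin` fits entirely
        if ((r - cr) / max(ar - margin, 1e-6)) ** 2 + (
            (c - cc) / max(ac - margin, 1e-6)
        ) ** 2 <= 1.0:
            return (r, c)
    raise PlacementError(
        f"could not place a nodule of extent {margin:.1f}px inside the lung fields"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom slice and its ground truth.

    Returns ``(image, truth)`` where ``image`` is a ``uint8`` array (values in
    ``[0, spec.levels - 1]``) and ``truth`` carries the clean nodule mask
    (drawn before noise), the class label, centers and radii.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    L = spec.levels
    body_c, body_ax, lungs, lung_ax = _lung_geometry(spec)

    img = np.full((h, w), float(spec.background_intensity))
    body = _ellipse_mask((h, w), body_c, body_ax)
    img[body] = spec.body_intensity
    lung_mask = np.zeros((h, w), bool)
    for lc in lungs:
        lung_mask |= _ellipse_mask((h, w), lc, lung_ax)
    lung_mask &= body
    img[lung_mask] = spec.lung_intensity

    # vessel-like clutter: short bright line segments inside the lung fields
    for _ in range(spec.vessel_count):
        (cr0, cc0) = lungs[int(rng.integers(0, 2))]
        r0 = cr0 + rng.uniform(-0.7, 0.7) * lung_ax[0]
        c0 = cc0 + rng.uniform(-0.7, 0.7) * lung_ax[1]
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(8, 25)
        width = rng.uniform(1.0, 2.0)
        ts = np.linspace(0.0, 1.0, int(length * 2))
        rr = np.clip(np.round(r0 + ts * length * np.cos(ang)).astype(int), 0, h - 1)
        cc_ = np.clip(np.round(c0 + ts * length * np.sin(ang)).astype(int), 0, w - 1)
        vessel = np.zeros((h, w), bool)
        vessel[rr, cc_] = True
        if width > 1.5:
            vessel |= np.roll(vessel, 1, axis=0) | np.roll(vessel, 1, axis=1)
        vessel &= lung_mask
        img[vessel] = spec.vessel_intensity

    # nodules
    mask = np.zeros((h, w), bool)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for i in range(spec.nodule_count):
        r0 = float(rng.uniform(*spec.nodule_radius_range))
        is_mal = bool(spec.malignant[i])
        extent = r0 * (1.0 + (spec.spiculation_amplitude if is_mal else 0.0)) + 2.0
        center = _place_nodule(lungs, lung_ax, extent, rng)
        if is_mal:
            nod = _spiculated_boundary(
                center, r0, spec.spiculation_amplitude, spec.spike_count_range, rng, (h, w)
            )
        else:
            nod = _benign_mask((h, w), center, r0, rng)
        img[nod] = spec.nodule_intensity
        mask |= nod
        centers.append(center)
        radii.append(r0)

    # mild per-pixel texture so histograms are not delta spikes
    if spec.texture_sigma > 0:
        img = img + rng.normal(0.0, spec.texture_sigma, size=img.shape)
    clean = np.clip(np.rint(img), 0, L - 1).astype(np.uint8)

    # salt-and-pepper: exactly round(density * N) distinct pixels, 0 or L-1
    noisy = clean.copy()
    n_corrupt = int(round(spec.noise_density * h * w))
    if n_corrupt:
        flat = rng.choice(h * w, size=n_corrupt, replace=False)
        salt = rng.random(n_corrupt) < 0.5
        vals = np.where(salt, L - 1, 0).astype(np.uint8)
        noisy.flat[flat] = vals

    truth = GroundTruth(
        nodule_mask=mask,
        label=spec.label,
        nodule_centers=centers,
        nodule_radii=radii,
    )
    return noisy, truth


def clean_render(spec: PhantomSpec) -> np.ndarray:
    """The same slice without salt-and-pepper noise (reference for PSNR)."""
    noise_free = replace(spec, noise_density=0.0)
    img, _ = generate_phantom(noise_free)
    return img


def generate_dataset(
    n: int,
    malignant_fraction: float,
    spec_template: PhantomSpec,
    seed: int,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate ``n`` labeled phantoms with a fixed class balance.

    Exactly ``round(n * malignant_fraction)`` items are malignant (round half
    up, so n=7 at 0.5 gives 4 malignant).  Per-item seeds are derived from the
    master ``seed`` through an independent bit generator, and the class
    sequence is a seeded shuffle, so the whole collection is reproducible.
    """
    if n < 2:
        raise ValueError("need n >= 2 to allow a train/test split")
    if not 0.0 <= malignant_fraction <= 1.0:
        raise ValueError("malignant_fraction must be in [0, 1]")
    n_mal = int(np.floor(n * malignant_fraction + 0.5))  # round half up
    labels = np.array([True] * n_mal + [False] * (n - n_mal))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for is_mal, s in zip(labels, item_seeds):
        spec = replace(
            spec_template,
            nodule_count=max(spec_template.nodule_count, 1),
            malignant=(bool(is_mal),) * max(spec_template.nodule_count, 1),
            seed=int(s),
        )
        out.append(generate_phantom(spec))
    return out


def save_phantom(
    image: np.ndarray,
    truth: GroundTruth,
    path: str | Path,
    mask_path: str | Path | None = None,
) -> None:
    """Write the slice (and optionally its mask) as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), image.astype(np.uint8))
    if mask_path is not None:
        iio.imwrite(Path(mask_path), (truth.nodule_mask * 255).astype(np.uint8))


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Dataset manifest (path, label, seed) as a CSV table."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "seed"])
        writer.writeheader()
        writer.writerows(rows)
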