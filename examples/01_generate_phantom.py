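"""Render one synthetic chest-CT slice with ground truth.

Builds a 256x256 phantom with a spiculated (malignant-like) nodule and 5%
salt-and-pepper noise, and prints what the generator knows about it: the
class label, nodule geometry, and how many pixels the noise corrupted.
"""

import numpy as np

from nodulecad.phantom import PhantomSpec, clean_render, generate_phantom

spec = PhantomSpec(seed=42, malignant=(True,), noise_density=0.05)
image, truth = generate_phantom(spec)
clean = clean_render(spec)

print(f"image: {image.shape[0]}x{image.shape[1]}, 8-bit, label {truth.label}")
print(f"nodule center (row, col): {tuple(round(v, 1) for v in truth.nodule_centers[0])}")
print(f"nodule radius: {truth.nodule_radii[0]:.1f} px, mask area {truth.nodule_mask.sum()} px")
corrupted = float((image != clean).mean())
print(f"corrupted pixel fraction: {corrupted:.4f} (requested {spec.noise_density})")
print(f"mean intensity inside nodule: {clean[truth.nodule_mask].mean():.1f}, "
      f"lung field ~{spec.lung_intensity} -> contrast "
      f"{clean[truth.nodule_mask].mean() - spec.lung_intensity:.0f} gray levels")
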