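"""LBP texture histograms separate smooth from spiculated nodules.

Extracts the detected nodule from a benign and a malignant phantom, builds
uniform-pattern LBP histograms and prints their chi-square distance — the
quantity the classifier ultimately exploits.
"""

import numpy as np

from nodulecad.otsu import compute_histogram, exhaustive_otsu
from nodulecad.phantom import PhantomSpec, generate_phantom
from nodulecad.preprocess import median_filter
from nodulecad.segment import apply_thresholds, extract_rois
from nodulecad.texture import LBPConfig, lbp_features

cfg = LBPConfig(neighbors=8, radius=1.0, uniform=True)
hists = {}
for label, malignant in (("benign", False), ("malignant", True)):
    img, truth = generate_phantom(PhantomSpec(seed=5, malignant=(malignant,)))
    filt = median_filter(img)
    t, _ = exhaustive_otsu(compute_histogram(filt), 3)
    rois = extract_rois(apply_thresholds(filt, t), filt)
    fv = lbp_features(rois[0].patch, cfg)
    hists[label] = fv.histogram
    top = np.argsort(fv.histogram)[::-1][:3]
    print(f"{label:<10} top uniform bins: " +
          ", ".join(f"{b} ({fv.histogram[b]:.2f})" for b in top))

a, b = hists["benign"], hists["malignant"]
denom = a + b
ok = denom > 0
chi2 = float(((a[ok] - b[ok]) ** 2 / denom[ok]).sum())
print(f"chi-square distance between class histograms: {chi2:.3f}")
print("(bins 0..8 count set bits of uniform codes, bin 9 pools non-uniform codes;")
print(" spiculated boundaries shift mass toward mixed/non-uniform patterns)")
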