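"""LBP codes, maps and histograms against bit-level oracles."""

import numpy as np
import pytest

from nodulecad.phantom import MALIGNANT, PhantomSpec, generate_dataset
from nodulecad.preprocess import median_filter
from nodulecad.texture import (
    LBPConfig,
    flip_code_map,
    is_uniform,
    lbp_code,
    lbp_features,
    lbp_map,
    rotate_code_map,
    uniform_bin_index,
)

from .conftest import naive_lbp_map


def test_code_all_neighbors_equal_center_is_all_ones():
    assert lbp_code(7, [7] * 8) == 255


def test_code_center_strictly_greater_is_zero():
    assert lbp_code(200, [100, 150, 0, 199, 12, 34, 56, 78]) == 0


def test_code_bit_by_bit_example():
    # bits 1,0,1,0,1,0,1,1 at positions 0..7 -> 1+4+16+64+128 = 213
    assert lbp_code(100, [100, 50, 200, 99, 101, 0, 100, 255]) == 213


def test_constant_image_gives_all_255_codes():
    codes = lbp_map(np.full((10, 10), 42, np.uint8))
    assert np.all(codes == 255)


def test_map_matches_naive_oracle_on_seeded_images():
    rng = np.random.default_rng(31)
    for _ in range(10):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.array_equal(lbp_map(img), naive_lbp_map(img))


def test_gray_shift_invariance():
    rng = np.random.default_rng(13)
    img = rng.integers(0, 200, (20, 20)).astype(float)
    assert np.array_equal(lbp_map(img), lbp_map(img + 37.0))


def test_radius_two_matches_oracle():
    rng = np.random.default_rng(17)
    img = rng.integers(0, 256, (18, 18)).astype(np.uint8)
    cfg = LBPConfig(neighbors=8, radius=2.0)
    assert np.array_equal(lbp_map(img, cfg), naive_lbp_map(img, 8, 2.0))


def test_image_too_small_rejected():
    with pytest.raises(ValueError):
        lbp_map(np.zeros((3, 3), np.uint8))


def test_config_validation():
    with pytest.raises(ValueError):
        LBPConfig(neighbors=2)
    with pytest.raises(ValueError):
        LBPConfig(radius=0.0)


# ------------------------------------------------------------- histograms


def test_constant_patch_histogram_mass_in_bin_255():
    fv = lbp_features(np.full((12, 12), 9, np.uint8))
    assert fv.histogram[255] == pytest.approx(1.0)
    assert fv.histogram.sum() == pytest.approx(1.0)


def test_histogram_sums_to_one_and_offset_invariant(rng):
    patch = rng.integers(0, 200, (16, 16)).astype(float)
    a = lbp_features(patch)
    b = lbp_features(patch + 11.0)
    assert a.histogram.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.array_equal(a.histogram, b.histogram)


def test_uniform_binning_matches_transition_count_oracle(rng):
    patch = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    cfg = LBPConfig(uniform=True)
    fv = lbp_features(patch, cfg)
    assert len(fv.histogram) == 10
    codes = lbp_map(patch)
    oracle = np.zeros(10)
    for code in codes.ravel():
        bits = [(int(code) >> s) & 1 for s in range(8)]
        transitions = sum(bits[s] != bits[(s + 1) % 8] for s in range(8))
        b = sum(bits) if transitions <= 2 else 9
        oracle[b] += 1
    oracle /= oracle.sum()
    assert np.allclose(fv.histogram, oracle)


def test_uniform_code_classification_examples():
    assert is_uniform(0b00000000, 8) and uniform_bin_index(0, 8) == 0
    assert is_uniform(0b11111111, 8) and uniform_bin_index(255, 8) == 8
    assert is_uniform(0b00001111, 8)
    assert not is_uniform(0b01010101, 8)
    assert uniform_bin_index(0b01010101, 8) == 9


# --------------------------------------------------- augmentation identities


def test_rotation_identity_on_code_maps(rng):
    img = rng.integers(0, 256, (20, 20)).astype(float)
    codes = lbp_map(img)
    for q in range(4):
        assert np.array_equal(
            rotate_code_map(codes, q), lbp_map(np.rot90(img, q))
        )


def test_flip_identity_on_code_maps(rng):
    img = rng.integers(0, 256, (20, 20)).astype(float)
    assert np.array_equal(flip_code_map(lbp_map(img)), lbp_map(np.fliplr(img)))


# -------------------------------------------------- class informativeness


def test_features_separate_phantom_classes_beyond_permutation_baseline():
    """Chi-square distance between class-mean histograms exceeds the 95th
    percentile of a label-permutation null."""
    from nodulecad.otsu import compute_histogram, exhaustive_otsu
    from nodulecad.segment import apply_thresholds, extract_rois

    data = generate_dataset(30, 0.5, PhantomSpec(), seed=23)
    feats, labels = [], []
    for img, truth in data:
        filt = median_filter(img)
        t, _ = exhaustive_otsu(compute_histogram(filt), 3)
        rois = extract_rois(apply_thresholds(filt, t), filt)
        if not rois:
            continue
        feats.append(lbp_features(rois[0].patch).histogram)
        labels.append(1 if truth.label == MALIGNANT else 0)
    feats = np.array(feats)
    labels = np.array(labels)

    def chi2_sep(y):
        a = feats[y == 1].mean(axis=0)
        b = feats[y == 0].mean(axis=0)
        denom = a + b
        ok = denom > 0
        return float(((a[ok] - b[ok]) ** 2 / denom[ok]).sum())

    observed = chi2_sep(labels)
    rng = np.random.default_rng(0)
    null = [chi2_sep(rng.permutation(labels)) for _ in range(200)]
    assert observed > np.percentile(null, 95)
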