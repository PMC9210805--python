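"""Metrics arithmetic, pipeline orchestration, optimizer comparison."""

import math

import numpy as np
import pytest

from nodulecad.classify import CNNConfig
from nodulecad.evaluate import (
    ConfusionMatrix,
    PipelineConfig,
    classification_metrics,
    compare_optimizers,
    dice,
    mse,
    psnr,
    run_pipeline,
)
from nodulecad.phantom import PhantomSpec, generate_dataset, generate_phantom


# ---------------------------------------------------------------- metrics


def test_mse_examples():
    a = np.zeros((4, 4), np.uint8)
    assert mse(a, a) == 0.0
    assert mse(a, np.full((4, 4), 255, np.uint8)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mse(a, np.zeros((3, 3), np.uint8))


def test_mse_matches_direct_summation(rng):
    a = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    b = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    direct = sum(
        ((int(x) - int(y)) / 255.0) ** 2 for x, y in zip(a.ravel(), b.ravel())
    ) / a.size
    assert mse(a, b) == pytest.approx(direct, abs=1e-12)


def test_psnr_log_arithmetic_and_sentinel():
    a = np.zeros((8, 8))
    b = np.full((8, 8), 25.5)  # normalized diff 0.1 -> MSE 0.01
    assert psnr(a, b) == pytest.approx(20.0)
    assert psnr(a, a) == math.inf


def test_classification_metrics_hand_example():
    acc, sens, spec = classification_metrics(ConfusionMatrix(9, 2, 8, 1))
    assert (acc, sens, spec) == pytest.approx((0.85, 0.9, 0.8))


def test_degenerate_confusion_matrix_yields_nan_specificity():
    acc, sens, spec = classification_metrics(ConfusionMatrix(10, 0, 0, 0))
    assert acc == 1.0 and sens == 1.0 and math.isnan(spec)
    with pytest.raises(ValueError):
        ConfusionMatrix(-1, 0, 0, 0)


def test_metrics_match_hand_formulas_on_random_counts(rng):
    for _ in range(20):
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
        acc, sens, spec = classification_metrics(ConfusionMatrix(tp, fp, tn, fn))
        assert acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))


def test_dice_examples():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    assert dice(a, b) == 1.0
    a[0, 0] = True
    assert dice(a, b) == 0.0
    b[0, 0] = True
    assert dice(a, b) == 1.0


# ---------------------------------------------------------------- pipeline


FAST = PipelineConfig(optimizer_kwargs=(("n", 15), ("max_iter", 60)))


def test_pipeline_blank_phantom_reports_no_lesion():
    img, _ = generate_phantom(PhantomSpec(nodule_count=0, seed=2))

    class Boom:
        def predict(self, X):  # must never be called
            raise AssertionError("classifier called without a lesion")

    result = run_pipeline(img, FAST, model=Boom())
    assert result.messages == ["no lesion found"]
    assert result.predictions == []


def test_pipeline_is_deterministic():
    img, _ = generate_phantom(PhantomSpec(seed=5, malignant=(True,)))
    r1 = run_pipeline(img, FAST)
    r2 = run_pipeline(img, FAST)
    assert r1.thresholds == r2.thresholds
    assert np.array_equal(r1.labels, r2.labels)
    assert np.array_equal(r1.filtered, r2.filtered)
    assert r1.messages == r2.messages


def test_pipeline_classifies_malignant_phantom():
    """A model trained on a small phantom set calls a spiculated nodule
    malignant through the full pipeline."""
    from nodulecad.evaluate import train_phantom_classifier

    model = train_phantom_classifier(n=40, seed=3, cnn_config=CNNConfig(seed=4, epochs=20))
    img, truth = generate_phantom(
        PhantomSpec(seed=1234, malignant=(True,), spiculation_amplitude=0.35)
    )
    result = run_pipeline(img, FAST, model=model)
    assert len(result.messages) == 1
    assert result.messages[0] == "Tumor is MALIGNANT"


def test_pipeline_reference_metrics():
    from nodulecad.phantom import clean_render

    spec = PhantomSpec(seed=6)
    img, _ = generate_phantom(spec)
    result = run_pipeline(img, FAST, reference=clean_render(spec))
    assert result.mse is not None and result.mse > 0
    assert result.psnr_db == pytest.approx(10 * math.log10(1 / result.mse))


# -------------------------------------------------------------- comparison


def test_compare_optimizers_fair_budget_and_oracle_ratio():
    dataset = generate_dataset(3, 0.5, PhantomSpec(), seed=9)
    reports = compare_optimizers(
        dataset, k=1, budget=1500, seed=9, oracle_check=True
    )
    assert [r.optimizer_name for r in reports] == ["cso", "pso", "ga"]
    evals = {r.evaluations for r in reports}
    assert evals == {3 * 1500}
    for r in reports:
        assert all(ratio >= 0.99 for ratio in r.sigma_ratios)
        assert 0.0 <= r.accuracy <= 1.0


def test_compare_single_optimizer_single_row_and_rerun_identical():
    dataset = generate_dataset(2, 0.5, PhantomSpec(), seed=4)
    r1 = compare_optimizers(dataset, optimizers=("cso",), k=1, budget=800, seed=4)
    r2 = compare_optimizers(dataset, optimizers=("cso",), k=1, budget=800, seed=4)
    assert len(r1) == 1
    assert r1[0].accuracy == r2[0].accuracy
    assert r1[0].sensitivity == r2[0].sensitivity
    assert r1[0].evaluations == r2[0].evaluations
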