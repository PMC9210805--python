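"""CNN and SVM classifiers: contracts, determinism, separability."""

import numpy as np
import pytest

from nodulecad.classify import (
    BENIGN,
    MALIGNANT,
    CNNClassifier,
    CNNConfig,
    NotTrainedError,
    Prediction,
    SVMConfig,
    build_cnn,
    format_prediction,
    predict,
    train_svm_baseline,
)


def dirichlet_dataset(n=200, seed=0, dim=256):
    """Two well-separated Dirichlet modes over histogram simplexes."""
    rng = np.random.default_rng(seed)
    alpha0 = np.ones(dim)
    alpha0[:dim // 2] = 8.0
    alpha1 = np.ones(dim)
    alpha1[dim // 2:] = 8.0
    X, y = [], []
    for i in range(n):
        cls = i % 2
        X.append(rng.dirichlet(alpha1 if cls else alpha0))
        y.append(cls)
    return np.array(X), np.array(y)


def split(X, y, frac=0.3, seed=1):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    cut = int(len(y) * frac)
    return X[idx[cut:]], y[idx[cut:]], X[idx[:cut]], y[idx[:cut]]


# ------------------------------------------------------------ construction


def test_forward_pass_outputs_probability_pair():
    model = build_cnn(CNNConfig(seed=3))
    out = model.forward(np.zeros((2, 32, 32)))
    assert out.shape == (2, 2)
    assert np.allclose(out.sum(axis=1), 1.0)


def test_identical_seeds_give_identical_initial_weights():
    a = build_cnn(CNNConfig(seed=9))
    b = build_cnn(CNNConfig(seed=9))
    c = build_cnn(CNNConfig(seed=10))
    assert a.parameter_hash() == b.parameter_hash()
    assert a.parameter_hash() != c.parameter_hash()


def test_single_block_pooling_arithmetic():
    model = build_cnn(CNNConfig(conv_blocks=((4, 3, 2),), seed=0))
    dense = model.layers[-3]  # first dense after flatten
    assert dense.W.shape[0] == 4 * 16 * 16  # 32 -> pool 2 -> 16


def test_incompatible_pooling_depth_rejected():
    with pytest.raises(ValueError):
        CNNConfig(input_size=20, conv_blocks=((8, 3, 2), (8, 3, 2), (8, 3, 2)))


# ------------------------------------------------------------- training


def test_separable_histograms_reach_high_heldout_accuracy():
    X, y = dirichlet_dataset()
    Xtr, ytr, Xte, yte = split(X, y)
    model = build_cnn(CNNConfig(input_mode="histogram", seed=4, epochs=30))
    report = model.fit(Xtr, ytr)
    assert len(report.epoch_loss) == 30
    preds = np.array([p.label == MALIGNANT for p in model.predict(Xte)])
    acc = float(np.mean(preds.astype(int) == yte))
    assert acc >= 0.95


def test_permuted_labels_fall_to_chance():
    X, y = dirichlet_dataset(seed=5)
    rng = np.random.default_rng(6)
    y = rng.permutation(y)
    Xtr, ytr, Xte, yte = split(X, y)
    model = build_cnn(CNNConfig(input_mode="histogram", seed=4, epochs=30))
    model.fit(Xtr, ytr)
    preds = np.array([p.label == MALIGNANT for p in model.predict(Xte)])
    acc = float(np.mean(preds.astype(int) == yte))
    assert 0.35 <= acc <= 0.65


def test_training_is_deterministic_given_seed():
    X, y = dirichlet_dataset(n=60, seed=7)
    runs = []
    for _ in range(2):
        model = build_cnn(CNNConfig(input_mode="histogram", seed=8, epochs=5))
        model.fit(X, y)
        runs.append(model.parameter_hash())
    assert runs[0] == runs[1]


def test_single_class_dataset_rejected():
    X = np.random.default_rng(0).random((10, 256))
    with pytest.raises(ValueError):
        build_cnn(CNNConfig(input_mode="histogram")).fit(X, np.zeros(10, int))
    with pytest.raises(ValueError):
        train_svm_baseline(X, np.zeros(10, int))


# ------------------------------------------------------------- prediction


def test_untrained_model_refuses_to_predict():
    with pytest.raises(NotTrainedError):
        build_cnn().predict(np.zeros((1, 32, 32)))


def test_decision_boundary_rule_is_geq():
    model = build_cnn(CNNConfig(input_mode="histogram", input_dim=4))
    model.trained = True
    model.forward = lambda X: np.array([[0.5, 0.5], [0.51, 0.49]])
    labels = [p.label for p in model.predict(np.zeros((2, 4)))]
    assert labels == [MALIGNANT, BENIGN]


def test_batch_prediction_equals_per_item():
    X, y = dirichlet_dataset(n=40, seed=2)
    model = build_cnn(CNNConfig(input_mode="histogram", seed=1, epochs=5))
    model.fit(X, y)
    batch = predict(model, X[:8])
    singles = [predict(model, X[i : i + 1])[0] for i in range(8)]
    assert [p.label for p in batch] == [p.label for p in singles]
    assert np.allclose([p.score for p in batch], [p.score for p in singles])


def test_verdict_line_format():
    assert format_prediction(Prediction(MALIGNANT, 0.9)) == "Tumor is MALIGNANT"
    assert format_prediction(Prediction(BENIGN, 0.1)) == "Tumor is BENIGN"


# ------------------------------------------------------------ persistence


def test_save_load_roundtrip(tmp_path):
    X, y = dirichlet_dataset(n=40, seed=3)
    model = build_cnn(CNNConfig(input_mode="histogram", seed=5, epochs=3))
    model.fit(X, y)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = CNNClassifier.load(path)
    assert loaded.parameter_hash() == model.parameter_hash()
    assert np.allclose(loaded.predict_proba(X), model.predict_proba(X))


# ------------------------------------------------------------------- SVM


def test_svm_baseline_on_separable_data():
    X, y = dirichlet_dataset(seed=11)
    Xtr, ytr, Xte, yte = split(X, y)
    svm = train_svm_baseline(Xtr, ytr, SVMConfig(seed=0))
    preds = np.array([p.label == MALIGNANT for p in svm.predict(Xte)])
    assert float(np.mean(preds.astype(int) == yte)) >= 0.95
    scores = [p.score for p in svm.predict(Xte)]
    assert all(0.0 <= s <= 1.0 for s in scores)


def test_svm_permuted_labels_near_chance():
    X, y = dirichlet_dataset(seed=13)
    y = np.random.default_rng(14).permutation(y)
    Xtr, ytr, Xte, yte = split(X, y)
    svm = train_svm_baseline(Xtr, ytr)
    preds = np.array([p.label == MALIGNANT for p in svm.predict(Xte)])
    assert 0.3 <= float(np.mean(preds.astype(int) == yte)) <= 0.7
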