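"""Quality metrics, pipeline orchestration and the optimizer comparison.

Metrics follow the standard definitions: MSE is the mean squared intensity
difference on the normalized [0, 1] scale, PSNR = 10*log10(1 / MSE) in dB
(infinite for identical images), and accuracy / sensitivity / specificity
derive from a TP/FP/TN/FN confusion matrix.

``run_pipeline`` realizes the full detection chain on one slice:
median denoise -> metaheuristic multilevel-Otsu thresholding -> candidate
ROI extraction -> LBP features -> benign/malignant classification, and
reports the verdict line ("Tumor is MALIGNANT" / "Tumor is BENIGN") or
"no lesion found" when no candidate survives.

``compare_optimizers`` runs cuckoo search, PSO and GA over the same phantom
set under one shared objective-evaluation budget (asserted from the traces)
and reports a row of MSE, PSNR, specificity, sensitivity and accuracy per
optimizer; classification metrics there are pixel-level, comparing the
extracted ROI union against the ground-truth nodule mask, so the comparison
needs no trained classifier.

The ``*_study`` functions are the package's reproducible experiments on
synthetic phantoms; they power both the test suite and the acceptance
script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import classify as _classify
from . import optimize as _optimize
from .otsu import (
    Histogram,
    ThresholdSet,
    compute_histogram,
    exhaustive_otsu,
    make_objective,
)
from .phantom import (
    BENIGN,
    MALIGNANT,
    GroundTruth,
    PhantomSpec,
    clean_render,
    generate_dataset,
    generate_phantom,
)
from .preprocess import MedianFilterConfig, median_filter
from .segment import apply_thresholds, extract_rois, roi_union_mask
from .texture import LBPConfig, flip_code_map, lbp_map, rotate_code_map

__all__ = [
    "ConfusionMatrix",
    "QualityReport",
    "PipelineConfig",
    "PipelineResult",
    "mse",
    "psnr",
    "classification_metrics",
    "dice",
    "run_pipeline",
    "compare_optimizers",
    "gaussian_mixture_histogram",
]


# ------------------------------------------------------------------ metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts of a two-class decision."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mse(a: np.ndarray, b: np.ndarray, levels: int = 256) -> float:
    """Mean squared difference on the normalized [0, 1] intensity scale."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    scale = levels - 1
    return float(np.mean(((a - b) / scale) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, levels: int = 256) -> float:
    """10*log10(1 / MSE) in dB; +inf for identical images (MSE = 0)."""
    m = mse(a, b, levels)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / m)


def classification_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a denominator is 0."""
    acc = (cm.tp + cm.tn) / cm.total if cm.total else math.nan
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else math.nan
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else math.nan
    return acc, sens, spec


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


# ------------------------------------------------------- histogram fixtures


def gaussian_mixture_histogram(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float] | None = None,
    n_pixels: int = 65536,
    levels: int = 256,
    seed: int = 0,
) -> Histogram:
    """Histogram of a sampled Gaussian mixture, clipped to [0, L-1].

    The standard multimodal fixture for thresholding experiments: a bimodal
    mixture (e.g. means 60/180, sd 10) has a clear two-class structure, a
    trimodal one a three-class structure.
    """
    rng = np.random.default_rng(seed)
    k = len(means)
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    comp = rng.choice(k, size=n_pixels, p=w)
    vals = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
    vals = np.clip(np.rint(vals), 0, levels - 1).astype(np.int64)
    return Histogram.from_counts(np.bincount(vals, minlength=levels))


# ------------------------------------------------------------- the pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, in one (hashable) place."""

    median: MedianFilterConfig = MedianFilterConfig()
    optimizer: str = "cso"
    k: int = 3
    optimizer_kwargs: tuple[tuple[str, object], ...] = ()
    min_area: int = 30
    max_area: int | None = None
    lesion_class: int | None = None
    lbp: LBPConfig = LBPConfig()
    patch_size: int = 32
    seed: int = 0


@dataclass
class QualityReport:
    """Table-row of the paper-style metric set for one configuration."""

    optimizer_name: str
    mse: float
    psnr_db: float
    specificity: float
    sensitivity: float
    accuracy: float
    seed: int
    evaluations: int = 0
    config: dict = field(default_factory=dict)
    sigma_ratios: list[float] = field(default_factory=list)


@dataclass
class PipelineResult:
    """Artifacts of one single-slice run (mirrors the staged figures)."""

    filtered: np.ndarray
    thresholds: ThresholdSet
    labels: np.ndarray
    rois: list
    predictions: list
    messages: list[str]
    mse: float | None = None
    psnr_db: float | None = None


def roi_code_map(patch: np.ndarray, lbp: LBPConfig, size: int = 32) -> np.ndarray:
    """LBP code map of a patch, edge-padded back to ``size`` x ``size``.

    ``lbp_map`` trims a border of width ceil(R); replicating the outermost
    codes restores the fixed input size the CNN expects.
    """
    codes = lbp_map(patch, lbp)
    pr = size - codes.shape[0]
    pc = size - codes.shape[1]
    if pr < 0 or pc < 0:
        raise ValueError("patch larger than the requested code-map size")
    return np.pad(
        codes,
        ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)),
        mode="edge",
    )


def _optimize_thresholds(
    image: np.ndarray, config: PipelineConfig
) -> tuple[ThresholdSet, object]:
    hist = compute_histogram(image)
    obj = make_objective(hist)
    kwargs = dict(config.optimizer_kwargs)
    kwargs.setdefault("k", config.k)
    kwargs.setdefault("seed", config.seed)
    best, trace = _optimize.search(obj, config.optimizer, **kwargs)
    return best.thresholds, trace


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    model=None,
    reference: np.ndarray | None = None,
) -> PipelineResult:
    """Denoise -> optimize thresholds -> segment -> LBP -> classify.

    ``reference`` (a clean image) enables the MSE/PSNR entries of the
    result.  When no candidate ROI survives, no classifier is called and the
    single message is ``no lesion found``.
    """
    config = config or PipelineConfig()
    filtered = median_filter(image, config.median)
    thresholds, _ = _optimize_thresholds(filtered, config)
    labels = apply_thresholds(filtered, thresholds)
    rois = extract_rois(
        labels,
        filtered,
        min_area=config.min_area,
        max_area=config.max_area,
        lesion_class=config.lesion_class,
        patch_size=config.patch_size,
    )
    predictions = []
    messages = []
    if not rois:
        messages.append("no lesion found")
    elif model is not None:
        for roi in rois:
            code = roi_code_map(roi.patch, config.lbp, config.patch_size)
            pred = model.predict(code[None])[0]
            predictions.append(pred)
            messages.append(_classify.format_prediction(pred))
    result = PipelineResult(
        filtered=filtered,
        thresholds=thresholds,
        labels=labels,
        rois=rois,
        predictions=predictions,
        messages=messages,
    )
    if reference is not None:
        result.mse = mse(filtered, reference)
        result.psnr_db = psnr(filtered, reference)
    return result


# --------------------------------------------------- optimizer comparison


def compare_optimizers(
    dataset: list[tuple[np.ndarray, GroundTruth]],
    cleans: list[np.ndarray] | None = None,
    optimizers: Sequence[str] = ("cso", "pso", "ga"),
    k: int = 3,
    budget: int = 2000,
    seed: int = 0,
    config: PipelineConfig | None = None,
    oracle_check: bool = False,
) -> list[QualityReport]:
    """One Table-style row per optimizer under an equal evaluation budget.

    Pixel-level confusion (extracted ROI union vs ground-truth mask) yields
    the classification metrics; MSE/PSNR compare the filtered image against
    the clean render when provided.  Raises if the per-image evaluation
    counts ever differ between optimizers (budget fairness).  With
    ``oracle_check`` (k <= 3) each report also carries the per-image ratio
    of the achieved sigma_B^2 to the exhaustive optimum.
    """
    config = config or PipelineConfig(k=k)
    reports: list[QualityReport] = []
    eval_counts: dict[str, list[int]] = {}
    oracle_best: dict[int, float] = {}
    for name in optimizers:
        tp = fp = tn = fn = 0
        mses: list[float] = []
        counts: list[int] = []
        ratios: list[float] = []
        for i, (image, truth) in enumerate(dataset):
            filtered = median_filter(image, config.median)
            hist = compute_histogram(filtered)
            obj = make_objective(hist)
            best, trace = _optimize.search(
                obj, name, k=k, seed=seed + i, max_evaluations=budget
            )
            counts.append(trace.evaluations)
            if oracle_check:
                if i not in oracle_best:
                    oracle_best[i] = exhaustive_otsu(hist, k)[1]
                ratios.append(best.fitness / oracle_best[i])
            labels = apply_thresholds(filtered, best.thresholds)
            rois = extract_rois(
                labels,
                filtered,
                min_area=config.min_area,
                max_area=config.max_area,
                lesion_class=config.lesion_class,
            )
            pred_mask = roi_union_mask(rois, image.shape)
            gt = truth.nodule_mask
            tp += int((pred_mask & gt).sum())
            fp += int((pred_mask & ~gt).sum())
            tn += int((~pred_mask & ~gt).sum())
            fn += int((~pred_mask & gt).sum())
            if cleans is not None:
                mses.append(mse(filtered, cleans[i]))
        eval_counts[name] = counts
        acc, sens, spec = classification_metrics(
            ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        )
        m = float(np.mean(mses)) if mses else math.nan
        reports.append(
            QualityReport(
                optimizer_name=name,
                mse=m,
                psnr_db=(10 * math.log10(1 / m) if m and m > 0 else math.inf),
                specificity=spec,
                sensitivity=sens,
                accuracy=acc,
                seed=seed,
                evaluations=int(np.sum(counts)),
                config={"k": k, "budget": budget},
                sigma_ratios=ratios,
            )
        )
    baseline = eval_counts[optimizers[0]]
    for name in optimizers[1:]:
        if eval_counts[name] != baseline:
            raise RuntimeError("evaluation budgets differ between optimizers")
    return reports


def reports_to_csv(reports: list[QualityReport], path) -> None:
    """Comparison table in the metric order MSE, PSNR, spec, sens, acc."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["optimizer", "MSE", "PSNR_dB", "specificity", "sensitivity", "accuracy"]
        )
        for r in reports:
            w.writerow(
                [
                    r.optimizer_name,
                    f"{r.mse:.6f}",
                    f"{r.psnr_db:.3f}",
                    f"{100 * r.specificity:.3f}",
                    f"{100 * r.sensitivity:.3f}",
                    f"{100 * r.accuracy:.3f}",
                ]
            )


# ----------------------------------------------------------------- studies


def k1_agreement_study(
    optimizer: str = "cso",
    runs: int = 100,
    seed: int = 0,
    n: int = 25,
    pa: float = 0.25,
    max_iter: int = 200,
    tolerance: int = 1,
) -> dict:
    """Single-threshold agreement with the exhaustive oracle.

    Each run draws a fresh bimodal histogram (means 60/180, sd 25 — the
    modes overlap, so every bin carries mass and the optimum is unique
    rather than a plateau spanning an empty gap) and counts a hit when the
    metaheuristic threshold lands within ``tolerance`` gray levels of the
    enumerated optimum.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(runs):
        hseed, oseed = rng.integers(0, 2**31 - 1, size=2)
        hist = gaussian_mixture_histogram([60, 180], [25, 25], seed=int(hseed))
        (t_star, _), obj = exhaustive_otsu(hist, 1), make_objective(hist)
        kwargs: dict = {"k": 1, "seed": int(oseed)}
        if optimizer == "cso":
            kwargs.update(n=n, pa=pa, max_iter=max_iter)
        best, _ = _optimize.search(obj, optimizer, **kwargs)
        if abs(best.thresholds.thresholds[0] - t_star.thresholds[0]) <= tolerance:
            hits += 1
    return {"hits": hits, "runs": runs, "rate": hits / runs}


def k2_near_optimality_study(
    optimizer: str = "cso",
    runs: int = 100,
    seed: int = 0,
    budget: int = 6000,
    ratio: float = 0.99,
) -> dict:
    """Two-threshold near-optimality vs the exhaustive oracle.

    Trimodal histograms (means 50/130/210, sds 18/20/18, overlapping so the
    landscape has no trivial plateaus); a hit is a final sigma_B^2 of at
    least ``ratio`` times the enumerated optimum.  All optimizers run under
    the same evaluation ``budget``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    ratios = []
    for _ in range(runs):
        hseed, oseed = rng.integers(0, 2**31 - 1, size=2)
        hist = gaussian_mixture_histogram(
            [50, 130, 210], [18, 20, 18], seed=int(hseed)
        )
        _, f_star = exhaustive_otsu(hist, 2)
        obj = make_objective(hist)
        best, trace = _optimize.search(
            obj, optimizer, k=2, seed=int(oseed), max_evaluations=budget
        )
        r = best.fitness / f_star
        ratios.append(r)
        if r >= ratio:
            hits += 1
        if trace.evaluations != budget:
            raise RuntimeError("optimizer did not exhaust its budget")
    return {
        "hits": hits,
        "runs": runs,
        "rate": hits / runs,
        "mean_ratio": float(np.mean(ratios)),
    }


def median_filter_study(
    n_images: int = 20, seed: int = 0, spec: PhantomSpec | None = None
) -> dict:
    """PSNR of noisy-vs-clean and filtered-vs-clean over seeded phantoms."""
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_images):
        s = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        noisy, _ = generate_phantom(s)
        clean = clean_render(s)
        filtered = median_filter(noisy)
        rows.append(
            {
                "psnr_noisy": psnr(noisy, clean),
                "psnr_filtered": psnr(filtered, clean),
                "mse_filtered": mse(filtered, clean),
            }
        )
    gains = [r["psnr_filtered"] - r["psnr_noisy"] for r in rows]
    return {
        "rows": rows,
        "all_improved": all(g > 0 for g in gains),
        "mean_gain_db": float(np.mean(gains)),
        "mean_psnr_filtered": float(np.mean([r["psnr_filtered"] for r in rows])),
        "mean_mse_filtered": float(np.mean([r["mse_filtered"] for r in rows])),
    }


def segmentation_dice_study(
    n_images: int = 20,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Dice between extracted ROI union and ground truth on phantoms."""
    base = spec or PhantomSpec()
    config = config or PipelineConfig(
        optimizer_kwargs=(("n", 15), ("max_iter", 80)),
    )
    rng = np.random.default_rng(seed)
    dices = []
    for _ in range(n_images):
        s = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        image, truth = generate_phantom(s)
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        result = run_pipeline(image, cfg)
        pred = roi_union_mask(result.rois, image.shape)
        dices.append(dice(pred, truth.nodule_mask))
    return {"dice": dices, "mean_dice": float(np.mean(dices))}


def _dataset_code_maps(
    n: int,
    seed: int,
    spec: PhantomSpec | None = None,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Detection features for an n-image phantom set.

    Runs the detection front end (denoise, optimize, segment) per image and
    returns the LBP code map of the largest detected ROI; images where no
    ROI survives fall back to a central lung crop (kept in the sample so
    detection failures count against classification accuracy).
    """
    base = spec or PhantomSpec()
    config = config or PipelineConfig(
        optimizer_kwargs=(("n", 15), ("max_iter", 60)),
    )
    dataset = generate_dataset(n, 0.5, base, seed)
    X, y = [], []
    misses = 0
    for i, (image, truth) in enumerate(dataset):
        cfg = replace(config, seed=seed + 7919 * i)
        result = run_pipeline(image, cfg)
        if result.rois:
            patch = result.rois[0].patch
        else:
            misses += 1
            h, w = image.shape
            half = config.patch_size // 2
            patch = result.filtered[
                h // 2 - half : h // 2 + half, w // 3 - half : w // 3 + half
            ]
        X.append(roi_code_map(patch, config.lbp, config.patch_size))
        y.append(1 if truth.label == MALIGNANT else 0)
    return np.asarray(X), np.asarray(y), misses


def augment_code_maps(
    X: np.ndarray, y: np.ndarray, m: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """8x augmentation by exact code-map rotations and mirrors.

    Orientation carries no class information in this problem, and both
    transforms have exact LBP-code equivalents (spatial op + bit
    permutation), so no re-extraction is needed.
    """
    X_out, y_out = [], []
    for codes, label in zip(X, y):
        for q in range(4):
            rot = rotate_code_map(codes, q, m)
            X_out.append(rot)
            X_out.append(flip_code_map(rot, m))
            y_out.extend([label, label])
    return np.asarray(X_out), np.asarray(y_out)


def train_phantom_classifier(
    n: int = 120,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    cnn_config: "_classify.CNNConfig | None" = None,
) -> "_classify.CNNClassifier":
    """CNN trained on detection features from ``n`` fresh phantoms."""
    X, y, _ = _dataset_code_maps(n, seed, spec)
    cfg = cnn_config or _classify.CNNConfig(seed=seed + 2)
    model = _classify.CNNClassifier(cfg)
    model.fit(*augment_code_maps(X, y))
    return model


def _stratified_split(y: np.ndarray, test_fraction: float, rng) -> tuple:
    idx_train, idx_test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        idx_test.extend(idx[:n_test])
        idx_train.extend(idx[n_test:])
    return np.sort(idx_train), np.sort(idx_test)


def end_to_end_study(
    n: int = 200,
    seed: int = 0,
    permute_labels: bool = False,
    spec: PhantomSpec | None = None,
    cnn_config: "_classify.CNNConfig | None" = None,
) -> dict:
    """Full CSO+CNN+LBP pipeline on a balanced phantom set, 70/30 split.

    Returns held-out accuracy/sensitivity/specificity.  With
    ``permute_labels`` the training labels are shuffled (control: held-out
    accuracy should drop to chance).
    """
    X, y, misses = _dataset_code_maps(n, seed, spec)
    rng = np.random.default_rng(seed + 1)
    if permute_labels:
        y = rng.permutation(y)
    tr, te = _stratified_split(y, 0.3, rng)
    cfg = cnn_config or _classify.CNNConfig(seed=seed + 2)
    model = _classify.CNNClassifier(cfg)
    X_tr, y_tr = augment_code_maps(X[tr], y[tr])
    report = model.fit(X_tr, y_tr)
    preds = np.array(
        [1 if p.label == MALIGNANT else 0 for p in model.predict(X[te])]
    )
    yt = y[te]
    cm = ConfusionMatrix(
        tp=int(((preds == 1) & (yt == 1)).sum()),
        fp=int(((preds == 1) & (yt == 0)).sum()),
        tn=int(((preds == 0) & (yt == 0)).sum()),
        fn=int(((preds == 0) & (yt == 1)).sum()),
    )
    acc, sens, spec_ = classification_metrics(cm)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec_,
        "confusion": cm,
        "n_train": len(tr),
        "n_test": len(te),
        "detection_misses": misses,
        "final_train_accuracy": report.final_train_accuracy,
    }
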