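"""Metaheuristics: Levy sampling, elitism, determinism, oracle agreement."""

import numpy as np
import pytest

from nodulecad.evaluate import gaussian_mixture_histogram
from nodulecad.optimize import (
    CuckooConfig,
    GAConfig,
    PSOConfig,
    _repair,
    cuckoo_search,
    ga_search,
    levy_step,
    pso_search,
    search,
)
from nodulecad.otsu import (
    ConstantImageError,
    Histogram,
    between_class_variance,
    exhaustive_otsu,
    make_objective,
)


@pytest.fixture(scope="module")
def bimodal():
    return gaussian_mixture_histogram([60, 180], [25, 25], seed=99)


# ------------------------------------------------------------- Levy steps


def test_levy_deterministic_under_fixed_state():
    a = levy_step(1.5, 1.0, np.random.default_rng(3), size=10)
    b = levy_step(1.5, 1.0, np.random.default_rng(3), size=10)
    assert np.array_equal(a, b)


def test_levy_zero_scale_gives_zero_displacement():
    steps = levy_step(1.5, 0.0, np.random.default_rng(0), size=100)
    assert np.all(steps == 0.0)


def test_levy_gamma_validation():
    rng = np.random.default_rng(0)
    for bad in (0.5, 1.0, 3.5):
        with pytest.raises(ValueError):
            levy_step(bad, 1.0, rng)


def test_levy_tail_heavier_than_gaussian():
    """P(|step| > q) at a high Gaussian quantile far exceeds the Gaussian tail."""
    from scipy import stats

    rng = np.random.default_rng(42)
    steps = levy_step(1.5, 1.0, rng, size=100_000)
    sigma = np.median(np.abs(steps)) / stats.norm.ppf(0.75)  # robust scale
    q = 4.0 * sigma
    tail = float(np.mean(np.abs(steps) > q))
    gauss_tail = 2 * stats.norm.sf(4.0)
    assert tail > 10 * gauss_tail


# ---------------------------------------------------------------- repair


def test_repair_yields_valid_threshold_vectors(rng):
    X = rng.normal(128, 200, size=(500, 3))
    V = _repair(X, 3, 256)
    assert V.min() >= 0 and V.max() <= 254
    assert np.all(np.diff(V, axis=1) >= 1)


# ------------------------------------------------------------ cuckoo search


def test_cuckoo_degenerate_single_nest_single_iteration(bimodal):
    obj = make_objective(bimodal)
    cfg = CuckooConfig(n=1, pa=0.0, max_iter=1, k=1, seed=5)
    best, trace = cuckoo_search(obj, cfg)
    # one initial nest + one Levy proposal
    assert trace.evaluations == 2
    assert best.fitness == pytest.approx(
        between_class_variance(bimodal, best.thresholds)
    )


def test_cuckoo_trace_is_nondecreasing_and_seeded(bimodal):
    obj = make_objective(bimodal)
    cfg = CuckooConfig(k=1, seed=11, max_iter=50)
    best1, t1 = cuckoo_search(obj, cfg)
    best2, t2 = cuckoo_search(obj, cfg)
    assert t1.best_fitness_per_iteration == t2.best_fitness_per_iteration
    assert best1.thresholds == best2.thresholds
    arr = np.array(t1.best_fitness_per_iteration)
    assert np.all(np.diff(arr) >= 0)


def test_cuckoo_matches_exhaustive_k1(bimodal):
    t_star, _ = exhaustive_otsu(bimodal, 1)
    obj = make_objective(bimodal)
    hits = 0
    for s in range(10):
        best, _ = cuckoo_search(obj, CuckooConfig(k=1, seed=s))
        if abs(best.thresholds.thresholds[0] - t_star.thresholds[0]) <= 1:
            hits += 1
    assert hits >= 9


def test_constant_image_objective_propagates():
    counts = np.zeros(256, np.int64)
    counts[9] = 100
    with pytest.raises(ConstantImageError):
        make_objective(Histogram.from_counts(counts))


# ------------------------------------------------------------------- PSO


def test_pso_frozen_swarm_keeps_best_initial_particle(bimodal):
    obj = make_objective(bimodal)
    cfg = PSOConfig(n=10, max_iter=20, inertia=0.0, cognitive=0.0, social=0.0,
                    vmax=0.0, k=1, seed=2)
    _, trace = pso_search(obj, cfg)
    assert len(set(trace.best_fitness_per_iteration)) == 1


def test_pso_seeded_and_nondecreasing(bimodal):
    obj = make_objective(bimodal)
    cfg = PSOConfig(k=1, seed=4, max_iter=60)
    b1, t1 = pso_search(obj, cfg)
    b2, t2 = pso_search(obj, cfg)
    assert t1.best_fitness_per_iteration == t2.best_fitness_per_iteration
    assert b1.thresholds == b2.thresholds
    assert np.all(np.diff(t1.best_fitness_per_iteration) >= 0)


def test_pso_matches_exhaustive_k1(bimodal):
    t_star, _ = exhaustive_otsu(bimodal, 1)
    obj = make_objective(bimodal)
    hits = 0
    for s in range(10):
        best, _ = pso_search(obj, PSOConfig(k=1, seed=s))
        if abs(best.thresholds.thresholds[0] - t_star.thresholds[0]) <= 1:
            hits += 1
    assert hits >= 9


# -------------------------------------------------------------------- GA


def test_ga_no_variation_keeps_best_constant(bimodal):
    obj = make_objective(bimodal)
    cfg = GAConfig(n=10, max_iter=15, crossover_rate=0.0, mutation_rate=0.0,
                   k=2, seed=6)
    _, trace = ga_search(obj, cfg)
    assert len(set(trace.best_fitness_per_iteration)) == 1


def test_ga_seeded_and_nondecreasing(bimodal):
    obj = make_objective(bimodal)
    cfg = GAConfig(k=1, seed=8, max_iter=40)
    b1, t1 = ga_search(obj, cfg)
    b2, t2 = ga_search(obj, cfg)
    assert t1.best_fitness_per_iteration == t2.best_fitness_per_iteration
    assert b1.thresholds == b2.thresholds
    assert np.all(np.diff(t1.best_fitness_per_iteration) >= 0)


def test_ga_matches_exhaustive_k1(bimodal):
    t_star, _ = exhaustive_otsu(bimodal, 1)
    obj = make_objective(bimodal)
    hits = 0
    for s in range(10):
        best, _ = ga_search(obj, GAConfig(k=1, seed=s))
        if abs(best.thresholds.thresholds[0] - t_star.thresholds[0]) <= 1:
            hits += 1
    assert hits >= 9


# ---------------------------------------------------------------- budgets


@pytest.mark.parametrize("name", ["cso", "pso", "ga"])
def test_evaluation_budget_is_hit_exactly(bimodal, name):
    obj = make_objective(bimodal)
    _, trace = search(obj, name, k=2, seed=1, max_evaluations=777)
    assert trace.evaluations == 777


def test_unknown_optimizer_rejected(bimodal):
    with pytest.raises(ValueError):
        search(make_objective(bimodal), "abc", k=1)


def test_config_validation():
    with pytest.raises(ValueError):
        CuckooConfig(gamma=1.0)
    with pytest.raises(ValueError):
        CuckooConfig(pa=1.5)
    with pytest.raises(ValueError):
        GAConfig(n=1)
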