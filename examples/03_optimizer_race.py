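"""Cuckoo search vs PSO vs GA under one shared evaluation budget.

Races the three metaheuristics on the same phantom set (k=1 threshold so
the exhaustive optimum is cheap to verify) and prints a comparison table of
pixel-level segmentation metrics in the order MSE-less studies use:
specificity, sensitivity, accuracy, plus how close each search came to the
enumerated Otsu optimum.
"""

import numpy as np

from nodulecad.evaluate import compare_optimizers
from nodulecad.phantom import PhantomSpec, generate_dataset

dataset = generate_dataset(5, 0.5, PhantomSpec(), seed=3)
reports = compare_optimizers(dataset, k=1, budget=1500, seed=3, oracle_check=True)

print(f"{'optimizer':<10}{'spec %':>9}{'sens %':>9}{'acc %':>9}{'sigma ratio':>13}{'evals':>8}")
for r in reports:
    print(
        f"{r.optimizer_name:<10}{100 * r.specificity:>9.3f}{100 * r.sensitivity:>9.3f}"
        f"{100 * r.accuracy:>9.3f}{np.mean(r.sigma_ratios):>13.5f}{r.evaluations:>8}"
    )
print("(sigma ratio = achieved sigma_B^2 / exhaustive optimum, mean over images;")
print(" identical eval counts show the comparison is budget-fair)")
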