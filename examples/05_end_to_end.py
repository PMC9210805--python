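"""Full pipeline: train the CNN on phantoms, then diagnose a new slice.

Trains the small CNN on LBP code maps from 60 phantoms (a quick, reduced
version of the package's 200-phantom study), then runs the complete
detection chain — denoise, cuckoo-search Otsu, ROI extraction, LBP, CNN —
on two unseen slices and prints the verdict lines.
"""

from nodulecad.evaluate import PipelineConfig, run_pipeline, train_phantom_classifier
from nodulecad.phantom import PhantomSpec, generate_phantom

print("training CNN on 60 phantoms (LBP code maps, 8x rotation/mirror augmentation)...")
model = train_phantom_classifier(n=60, seed=3)

cfg = PipelineConfig(optimizer_kwargs=(("n", 15), ("max_iter", 60)))
for seed, malignant in ((1234, True), (4321, False)):
    img, truth = generate_phantom(PhantomSpec(seed=seed, malignant=(malignant,)))
    result = run_pipeline(img, cfg, model=model)
    print(f"slice seed {seed} (truth {truth.label}):")
    print(f"  thresholds {result.thresholds.thresholds}, {len(result.rois)} ROI(s)")
    for line in result.messages:
        print(f"  {line}  (score {result.predictions[0].score:.3f})"
              if result.predictions else f"  {line}")
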