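# Methods

This note records the models, conventions and numerical choices behind
`nodulecad`, in the order the pipeline runs.

## Phantom generator

The generator renders a stylized axial chest-CT slice at 8-bit depth,
256×256 by default. Geometry: a body ellipse (intensity 175) on a dark
table/air background (10), two lung-field ellipses (70), short bright
streaks as vessel clutter (150), and nodules (240). Mild Gaussian texture
(σ = 3 gray levels) is added so histograms are not delta spikes, then the
image is quantized and salt-and-pepper noise corrupts exactly
`round(density · N)` distinct pixels, each set to 0 or 255 with equal
probability. Defaults: one nodule, radius 8–14 px, noise density 0.05,
six vessels.

Nodule classes differ in boundary texture: benign nodules are smooth
ellipses with mild random eccentricity; malignant nodules are disks whose
radius is modulated as r(θ) = r₀(1 + a·Σⱼ sin(fⱼθ + φⱼ)) with 6–10 random
spike components and the modulation normalized so its peak equals the
spiculation amplitude a (default 0.3, i.e. spikes up to 30 % of the
radius). Normalizing to the peak keeps the radius positive and the
amplitude parameter interpretable as "fraction of radius".

The nodule is brightest by design (240 vs 175 body wall): nodules are
hyperdense in CT, and making them the top intensity class lets "brightest
class = candidate lesion" hold with k = 3 thresholds. With only k = 2 the
optimizer merges nodule, body wall and vessels into one class and the body
ring contaminates the candidate set — hence the pipeline default k = 3.

What the phantoms do **not** emulate: Hounsfield calibration, 3-D partial
volume effects, reconstruction streaks, anatomical variability, or subtle
ground-glass lesions. Passing tests show the pipeline's machinery is
correct and that boundary texture is learnable; they do not certify
clinical performance.

Coordinates are (row, col), 0-based, origin top-left, half-open ranges.
All randomness flows through `numpy.random.default_rng(seed)`; per-item
seeds in datasets derive from the master seed, so every artifact is
bit-reproducible.

## Median filter

Plain square-window sample median (default 3×3), borders handled by
padding (`reflect`, i.e. mirrored edge pixels, by default; `replicate`
optional), delegated to `scipy.ndimage.median_filter`. Because padding
always yields a full window, the sample count is odd and no tie rule is
needed. The median is the minimizer of M(g) = Σ|xₖ − g|, which is covered
as a property test rather than used computationally.

## Otsu objective

With class i covering gray levels (x_{i−1}, x_i], x₀ = −1, x_{k+1} = L−1:
P_i = Σ p_g, m_i = Σ g·p_g / P_i (empty classes contribute zero), global
mean m_G, and σ_B² = Σ P_i (m_i − m_G)². The global variance is the
probability-weighted σ_G² = Σ p_g (g − m_G)², so τ = σ_B²/σ_G² ∈ [0, 1]
and the law of total variance σ_B² + σ_W² = σ_G² holds to numerical
precision — the suite checks this against an independently summed σ_W² on
random histograms. Evaluations use cumulative sums (O(k) per candidate,
vectorized over candidate batches). `exhaustive_otsu` enumerates all
C(L−1, k) threshold sets for k ≤ 3 and breaks ties toward the
lexicographically smallest set; it is the oracle the metaheuristics are
measured against.

## Metaheuristics

All three searchers work in continuous space and repair candidates
(round, clamp to [0, L−2], sort, force strict increase) before every
evaluation; fitness is σ_B² (monotone in τ for a fixed image).

* **Cuckoo search** (default n = 25 nests, Pa = 0.25, M = 200 iterations,
  α = 1.0 gray level, γ = 1.5): per iteration each nest emits a
  Lévy-flight proposal which replaces a uniformly chosen nest if fitter;
  then the worst ⌈Pa·n⌉ nests (never the incumbent best) are rebuilt by
  fresh Lévy flights. Lévy steps use Mantegna's algorithm with tail index
  γ ∈ (1, 3] (β = γ − 1); at γ = 3 the Mantegna scale degenerates and a
  Gaussian step is substituted. Only the iteration count M = 200 is
  externally prescribed; the remaining defaults follow common cuckoo-search
  practice.
* **PSO**: global-best swarm, inertia 0.72, cognitive/social 1.49,
  velocity clamp 40.
* **GA**: generational, tournament of 3, one-point crossover (0.9),
  per-gene uniform mutation (0.1), elitism of one.

Each searcher records best-fitness-per-iteration (non-decreasing by
elitism) and its evaluation count. An optional evaluation budget stops a
search mid-batch the moment the budget is spent, so comparative runs have
exactly equal evaluation counts — the comparison harness asserts this from
the traces.

Study fixtures are sampled Gaussian-mixture histograms. The bimodal
fixture uses means 60/180 with sd 25 so the modes overlap: with narrow
modes the inter-mode gap is empty and the Otsu optimum is a wide plateau,
making "agreement within ±1 gray level" meaningless; overlapping modes
give a unique optimum. The trimodal fixture (50/130/210, sd 18/20/18)
overlaps for the same reason.

## Segmentation and ROIs

Pixels are classified by interval membership (a pixel equal to a threshold
belongs to the lower class). Candidate lesions: the brightest class,
opened once with a 3×3 structuring element (detaches vessels), labeled
with 8-connectivity, filtered to areas in [30 px, 20 % of the image],
sorted largest-first. Each ROI carries its component mask, tight bounding
box, centroid, and a 32×32 grayscale patch cropped with a 25 % margin and
resized **without** anti-aliasing — the class signal lives in sharp
boundary steps, and smoothing them weakens the texture features.

## LBP features

Code = Σ_{s=0}^{m−1} 1[P_s − P_c ≥ 0]·2^s, m = 8 neighbors at radius
R = 1 by default; neighbor 0 is east, proceeding counterclockwise;
non-integer positions are sampled bilinearly. The comparison interpolates
the *differences* P_s − P_c rather than the raw intensities, so exact ties
(all corners equal to the center) remain exactly zero under floating-point
arithmetic and the t ≥ 0 convention is stable; this also makes codes
exactly invariant to global gray shifts. The map excludes a border of
width ⌈R⌉. Histograms are single-cell (ROIs are small), either all 2^m
raw-code bins or m + 2 uniform bins (codes with ≤ 2 circular transitions
binned by popcount, the rest pooled).

Two exact augmentation identities are exploited for training: rotating
the source by a quarter turn equals rotating the code map and bit-rolling
codes by m/4; mirroring equals flipping the map and permuting bits
s → m/2 − s. The training split is augmented 8× (4 rotations × mirror);
orientation carries no class information in this problem.

## Classifier

The CNN (NumPy implementation) consumes the 32×32 LBP code map scaled to
[0, 1]: two conv blocks (8 and 16 filters, 3×3, same padding, ReLU,
max-pool 2), a 32-unit dense ReLU layer and a 2-way softmax; Adam at
1e-3, cross-entropy, 30 epochs, batch size 16, everything seeded (He
initialization, shuffling). Max-pool backpropagation splits gradients
evenly among tied maxima, keeping training deterministic. A `histogram`
input mode feeds a raw LBP histogram through the dense head instead, for
experiments on which representation the classifier should consume. The
decision rule is MALIGNANT iff P(malignant) ≥ 0.5. The SVM baseline is an
RBF-kernel SVC (C = 10) on LBP histograms with a logistic squash of the
margin as its score.

## Metrics and studies

MSE is computed on the normalized [0, 1] intensity scale; PSNR =
10·log₁₀(1/MSE) dB with an infinite sentinel at MSE = 0 (reported in dB;
a percentage makes no sense for a log ratio). Denoising quality is
measured filtered-vs-clean against the phantom's noise-free render.
Accuracy, sensitivity and specificity follow the standard confusion-matrix
formulas; undefined rates (zero denominators) are returned as NaN, the
other metrics unaffected. Percentages print with 3 decimals.

The optimizer comparison reports classification metrics at the pixel
level — extracted-ROI union vs ground-truth mask — so it needs no trained
classifier and isolates segmentation quality from classifier capacity.

Study sizes: oracle-agreement studies use 100 runs each; the variance
decomposition checks 1000 random histograms; denoising and segmentation
studies use 20 phantoms; the end-to-end experiment uses 200 phantoms
(50/50 classes, stratified 70/30 split), with images whose detection
stage finds no ROI kept in the sample (a central lung crop stands in) so
detection failures count against classification accuracy. Inside these
studies the per-image threshold search runs a reduced cuckoo configuration
(15 nests, 60–80 iterations), which on phantom histograms reaches the same
plateau as the full configuration.

## Known limitations

* 2-D, 8-bit, single-slice only; no Hounsfield units, no volumetrics.
* The phantom's five-intensity structure makes thresholding much cleaner
  than clinical CT; Dice ≈ 0.99 here says the machinery is right, not that
  real nodules segment this well.
* The CNN is deliberately tiny and CPU-bound; it is not a modern detector.
* GA crossover is a no-op at k = 1 (one gene), where the search relies on
  mutation and selection.
* Exhaustive enumeration beyond k = 3 is rejected rather than attempted.
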