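# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `gobletseg`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Segmentation task and networks

The task is binary semantic segmentation of bright goblet cells (GCs) in
single-channel fluorescence tiles, followed by instance-free counting:
cells are the 8-connected components of the binarized probability map.

**DCAU-Net.** Encoder of `depth` stages (default 4, widths
`base_channels·2^s`, default 64/128/256/512), each a dual-channel
convolution block followed by 2×2 max-pooling:

- *Semantic channel*: a single 3×3 conv block in parallel with two stacked
  3×3 conv blocks; the two paths are **summed**, keeping the channel count
  fixed so the later element-wise fusion with the texture channel is
  defined. Each block is conv → batch norm → ReLU with an identity
  shortcut (1×1 projection when channel counts differ).
- *Texture channel*: k×1 then 1×k convolution (k odd, default 7), stride 1
  with same-padding so its output matches the semantic channel's shape;
  batch norm + ReLU after each.
- *Global channel attention* on the fused map I′ = semantic + texture:
  channel descriptor Iˢ by global average pooling, single-channel
  attention map Iᴬ by a pointwise 1×1 convolution, refined map
  Iᴿ = σ(Iᴬ)·Iˢ (the outer product of a C×1×1 descriptor and a 1×H×W
  gate), and the skip output Iᴿ ⊙ I′. A flag (`gate_prefusion`) instead
  multiplies the raw semantic features, for ablation.

The decoder mirrors the encoder: bilinear ×2 upsampling (half-pixel
alignment), a 1×1 channel reduction, concatenation with the stage's GCA
output, then two 3×3 conv blocks; a 1×1 convolution and sigmoid produce
the probability map at input resolution. Inputs must be divisible by
2^depth; violations raise immediately rather than silently padding.

**Baseline U-Net.** The classic architecture: double 3×3 conv + ReLU
blocks (no batch norm), 2×2 max-pooling, 2×2 stride-2 up-convolutions,
channel widths 64…1024, sigmoid head. At those widths it has ≈31.0M
parameters (the test suite checks the closed-form count). It trains with
binary cross-entropy under the identical loop.

Weights are He-normal initialized from a seeded generator; batch norm uses
batch statistics in training and running statistics (momentum 0.1) in
evaluation.

**Execution engine.** Both networks run on a compact reverse-mode autodiff
engine over float64 NumPy arrays (`gobletseg.nn.autodiff`): broadcast
arithmetic, ReLU/sigmoid/log/clip/power, reductions, im2col-based 2-D
convolution, 2×2 transposed convolution, 2×2 max-pooling, bilinear ×2
upsampling, batch normalization and channel concatenation. Every
primitive's gradient is verified against central finite differences in the
test suite. The engine favors clarity and exactness over speed, which is
why the shipped benchmarks use reduced depths and widths (below).

## Losses and training protocol

- Soft dice over the flattened batch: `1 − (2Σpg + ε)/(Σp + Σg + ε)`,
  ε = 10⁻⁶ (exposed).
- Focal loss, pixel mean of `−α(1−p)^γ g log p − (1−α) p^γ (1−g) log(1−p)`
  with γ = 2, α = 0.25 (the focal-loss reference defaults) and probability
  clamping at 10⁻⁷ for stability. At γ=0, α=0.5 it reduces to 0.5·BCE,
  which the tests exploit as an oracle.
- Compound loss 0.7·dice + 0.3·focal for DCAU-Net; plain BCE for the
  baseline.
- Adam, lr 10⁻⁴ default, step decay ×0.5 every 20 epochs (factor and
  period exposed; the decay factor is a package choice, not externally
  prescribed), early stopping on validation dice with patience 10, best
  validation checkpoint restored.
- Grouped k-fold cross-validation (default k=5): folds partition *cases*,
  sizes differing by at most one (16 cases → 4/3/3/3/3), and every tile
  follows its case, so no case ever appears in both train and validation.
  `train()` refuses leaking splits outright.

## Synthetic scenes

The generator (`gobletseg.synthetic`) emulates the statistical structure
of MBFM goblet-cell images; it is the package's test bed and benchmark
substrate, not an optics simulation.

Per `SceneParams` (defaults in parentheses):

- **Cell count**: Poisson with mean `target_density × area`
  (1500 cells/mm², within the 1050–2350 cells/mm² range typical of rabbit
  conjunctiva).
- **Cell shape**: rotated ellipses; area normal with mean 60 μm², sd
  15 μm² (GC sizes reported in vivo span roughly 46–100 μm²), eccentricity
  uniform in (0.3, 0.8) — moment eccentricities near 0.5, matching
  measured GC elongation. Ellipses give analytically known area and
  eccentricity for morphometry oracles.
- **Clustering**: with probability `cluster_prob` (0.15) a placement event
  spawns 2–4 mutually touching cells (neighbor centers closer than the sum
  of semi-minor axes), so components merge under 8-connectivity and
  counting undercounts — the bias direction seen with aggregated GCs.
  Isolated cells are placed with a 1.6 px exclusion halo so they never
  touch: with `cluster_prob = 0` every placed cell is its own component
  and density recovery is exact by construction. Cells keep ≥6 own pixels
  (surviving the default 5 px² minimum-area filter); overlap above 60% of
  a candidate's pixels is rejected; a saturated field stops placement
  after repeated failures (the recorded truth always reflects what was
  actually placed).
- **Background**: base level plus a smooth random field (amplitude 0.15)
  and multiplicative vessel shadows — smoothed random walks that only
  darken (depth 0.5), never brighten.
- **Artifacts**: small bright non-cell dots (20 /mm²) added to the image
  but never to the mask.
- **Noise**: additive Gaussian (sd 0.02 of full scale); output quantized
  to 16 bits.

A single `numpy` Generator seeded from `SceneParams.seed` drives
everything; equal seeds give bit-identical scenes. Mosaics derive one
child seed per grid position from `(seed, row, col)` via `SeedSequence`,
and record the physical tile pitch (e.g. 2.5 mm for an 8×8 grid covering
20×20 mm²).

What the generator does **not** model: point-spread function and defocus,
depth-of-field effects, motion artifacts, staining heterogeneity within a
cell, and real vessel topology. Passing tests on synthetic scenes
therefore demonstrate the correctness of the pipeline's algebra, training
dynamics and morphometry — not clinical-grade performance on real MBFM
images.

## Preprocessing

CLAHE (scikit-image implementation) with normalized clip limit 0.01 and an
8×8 contextual grid, applied to the full tile before cropping (both
config-overridable). Augmentation draws aligned random crops (uniform over
valid offsets) and expands each with right-angle rotations and horizontal/
vertical flips — right angles keep binary masks exact, so masks need no
interpolation. Augmentation multiplicity is
`n_crops × |rotations| × (1 + |flips|)`; no augmentation is applied at
evaluation time.

## Ground-truth bootstrap

Initial labels come from sectional thresholding: the tile is partitioned
into rectangles, each with its own threshold (foreground iff intensity
strictly exceeds it). `auto_section_thresholds` fills the grid with
per-section Otsu values — a reproducible, automated surrogate for what is
in practice a manual per-section adjustment; it is labeled as such and its
quality bar in the tests is deliberately low (bootstrap, not final).
A baseline U-Net trained on these masks yields rough predictions
(binarized at 0.5) for external manual refinement; the package reads and
writes editable 0/255 PNGs and JSON section-grid sidecars but contains no
annotation GUI.

## Metrics

Confusion counts are exact integers; recall = TP/(TP+FN), precision =
TP/(TP+FP), FPR = 1 − TN/(TN+FP), IoU = TP/(TP+FP+FN), and Dice =
2TP/(2TP+FP+FN) — the standard form, consistent with the identity
dice = 2·iou/(1+iou). When both masks are empty the overlap metrics are
defined as 1 and flagged (`degenerate`). The precision–recall curve scans
256 evenly spaced thresholds by default; AP integrates precision over
recall by the trapezoid rule with an anchor at recall 0; an empty ground
truth yields AP = NaN rather than an arbitrary number. Repeated runs
aggregate as sample mean ± sd per metric. Per-image evaluation is the
default; pooled-pixel aggregation is available by summing counts.

## Morphometry

Regions are 8-connected components (8-connectivity merges diagonal
contact, consistent with aggregated-GC undercounting); a minimum-area
filter (default 5 px², 0 disables) suppresses single-pixel noise.
`area_um2 = area_px · um_per_px²` exactly, so doubling the calibration
quadruples areas and quarters densities. Eccentricity comes from the
moment-matched ellipse, `e = √(1 − λ₂/λ₁)`, computed over the union of
unit pixel squares (the per-pixel 1/12 moment term), which removes most of
the small-region discretization bias; single-pixel regions get e = 0.
Residual rasterization error grows as regions shrink and as shapes
approach circularity: for semi-axes ≳7 px at eccentricity ≳0.6 it stays
within ±0.02, while near-circular cells with semi-axes ≲6 px can deviate
by up to ~0.05 — an inherent property of binary rasterization, not of the
estimator. Cells are counted in the tile containing their centroid,
avoiding double counting across mosaic tiles.

`density_agreement` reports the Pearson correlation of automated vs
reference densities, the mean auto/reference ratio, and the 2.5th/97.5th
percentiles of the relative error (the empirical 95% band).
`compare_timepoints` gives per-group mean ± sd of density and cell area;
sd is reported as NaN for single-member groups rather than invented.

## Benchmark problem sizes

The shipped benchmarks run on one CPU with reduced sizes, chosen once as
the package's standard scaled-down study:

- *Overfit check*: one 64×64 scene, 2-stage DCAU-Net (base width 8),
  Adam lr 10⁻³, combined loss below 0.05 within 200 iterations.
- *Held-out benchmark*: 40 scenes of 128×128 px at 1500 cells/mm², 10
  synthetic cases, 8 train / 2 held-out cases, 6 epochs at lr 10⁻³ —
  held-out Dice ≥ 0.85 and AP above the sectional-Otsu baseline on every
  held-out scene.
- *Mosaic*: 8×8 grid of 192×192 px tiles with a density ramp
  800 → 2400 cells/mm².

These sizes trade statistical power for runtime; the full-scale protocol
(2048×2048 tiles, 512×512 crops, depth-4 widths 64–512, 100 epochs at
lr 10⁻⁴) is what the defaults encode.

## Design choices where the design was open

- Semantic-path merge by summation (not concatenation), to keep channel
  counts equal for element-wise fusion.
- GCA gates the fused map I′ by default; a flag switches to the raw
  semantic features.
- Decoder skips concatenate the GCA output with upsampled features (U-Net
  convention); decoder upsampling is bilinear for DCAU-Net and learned
  2×2 up-convolution for the classic baseline (required to match its
  parameter count).
- Per-section Otsu stands in for manual sectional thresholds.
- Empty-vs-empty overlap metrics are 1 (flagged), avoiding 0/0.
- Binarization threshold 0.5 throughout; exposed everywhere it appears.

## Known limitations

- The NumPy engine is single-threaded apart from BLAS matmuls; full-scale
  training at publication sizes is impractical with it — the architecture
  and protocol are faithful, the shipped experiments are scaled down.
- Pixel-level metrics only; no instance-matching detection metrics.
- The generator's clustering model (2–4 cells at fixed contact geometry)
  is a simplification; real aggregates can be larger and denser, so the
  clustered undercount ratio measured on synthetic scenes should not be
  read as an estimate of the undercount on real tissue.
- No statistical hypothesis testing across timepoints; summaries are
  descriptive (mean ± sd), matching the analysis the pipeline is built to
  mirror.
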