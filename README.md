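# gobletseg

Automated segmentation and morphometry of conjunctival **goblet cells
(GCs)** in fluorescence microscopy images.

Goblet cells secrete the mucins that form the innermost layer of the tear
film; their loss accompanies dry eye disease and other ocular surface
conditions, so GC density and size are diagnostically useful quantities.
Moxifloxacin-based fluorescence microscopy (MBFM) images GCs non-invasively
as bright roundish blobs — distributed individually or in touching
clusters at roughly 1000–2400 cells/mm² — over an irregular background
shadowed by blood vessels. `gobletseg` turns such tiles into per-cell
measurements: it segments GCs with a dual-channel attention U-Net
(DCAU-Net), counts them per unit area, and reports cell area (μm²) and
eccentricity, including spatial density maps over mosaic acquisitions and
longitudinal comparisons.

Because in-vivo MBFM data are rarely shareable, the package ships a
first-class synthetic scene generator with exact ground truth that
emulates the MBFM image statistics; the whole pipeline is testable end to
end without any animal data.

## The model

DCAU-Net is a U-Net-shaped encoder–decoder in which each encoder stage is
a **dual-channel convolution (DCC)** block and each skip connection passes
through **global channel attention (GCA)**:

- the *semantic channel* runs a single 3×3 conv block in parallel with two
  stacked 3×3 blocks (5×5 effective receptive field) and sums the paths;
  each block is residual conv + batch norm + ReLU;
- the *texture channel* applies two asymmetric convolutions (k×1 then 1×k,
  default k=7), capturing elongated texture/boundary structure with 2k
  instead of k² weights per channel pair;
- the channels are fused element-wise, `I′ = semantic + texture`, and the
  GCA computes

  ```
  Iˢ[c] = 1/(H·W) Σᵢ Σⱼ I′[c,i,j]          (channel descriptor, GAP)
  Iᴬ     = conv1×1(I′)                      (1×H×W attention map)
  Iᴿ     = σ(Iᴬ) × Iˢ                       (outer product, C×H×W)
  skip   = Iᴿ ⊙ I′
  ```

  so each skip feature is gated jointly by a spatial sigmoid map and its
  channel's global average.

Training uses the compound loss `0.7·Dice + 0.3·Focal` (γ=2, α=0.25) with
Adam (lr 10⁻⁴, step decay ×0.5 every 20 epochs, early stopping) and
grouped k-fold cross-validation in which all tiles from one animal/case
share a fold. A standard U-Net trained with binary cross-entropy is
included as the baseline, and a sectional (per-section Otsu) thresholding
stage supports semi-automated ground-truth bootstrapping.

Segmentation quality is scored at pixel level — Dice, IoU, recall,
precision, false-positive rate, and the area under the precision–recall
curve — with Dice = 2·IoU/(1+IoU) holding identically. Morphometry treats
each 8-connected component of the binarized probability map as one cell;
touching cells merge, which reproduces the systematic undercounting of
aggregated GCs seen in practice.

The networks run on a small self-contained NumPy reverse-mode autodiff
engine (`gobletseg.nn`), gradient-checked against finite differences;
no GPU or deep-learning framework is required.

## Worked example

```python
import numpy as np
from gobletseg import SceneParams, generate_scene, extract_regions, density

params = SceneParams(width_px=256, height_px=256, um_per_px=1.0,
                     target_density=1500.0, seed=42)
scene = generate_scene(params)                       # exact ground truth
regions = extract_regions(scene.mask, params.um_per_px, min_area_px=5)
print(f"placed cells:        {len(scene.regions)}")
print(f"true density:        {scene.true_density:.1f} cells/mm^2")
print(f"segmented regions:   {len(regions)}")
print(f"estimated density:   {density(regions, params.area_mm2):.1f} cells/mm^2")
print(f"mean cell area:      {np.mean([r.area_um2 for r in regions]):.1f} um^2")
print(f"mean eccentricity:   {np.mean([r.eccentricity for r in regions]):.2f}")
```

prints

```
placed cells:        98
true density:        1495.4 cells/mm^2
segmented regions:   83
estimated density:   1266.5 cells/mm^2
mean cell area:      70.1 um^2
mean eccentricity:   0.55
```

98 cells were placed (Poisson around 1500 cells/mm² × 0.0655 mm²), but
connected-component counting on the mask finds 83 regions: the default
15% clustering rate makes touching cells merge, so the density estimate
undercounts the truth — the expected direction and magnitude for
aggregated GCs. With `cluster_prob=0` the estimate equals the truth
exactly. Mean area and eccentricity reflect the generator's cell-shape
distribution (60±15 μm², eccentricity 0.3–0.8; merged clusters inflate
the measured mean area).

The same pipeline is scriptable from the shell:

```sh
gobletseg simulate --config scene.yaml --out sim/ --count 8
gobletseg run --config scene.yaml --out run/   # simulate ... analyze
gobletseg evaluate --pred run/predict --gt run/simulate --out report/
```

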