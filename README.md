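# sitmap

Hip localization and sitting-posture classification from seat pressure
images.

A 32×32 pressure sensor array under a seat cushion produces a low-resolution
"pressure image" of a seated person (one pixel ≈ 11.5 mm).  Fixed-position
features break down as soon as the person rotates or shifts on the chair, so
`sitmap` first *finds the hips* and only then extracts features around them:

1. **Preprocessing** — threshold mask (0.45 × mean) cleaned by morphological
   opening/closing, 3×3 Gaussian smoothing, mask multiplication, then L1
   normalization: `dst(i,j) = scr(i,j) / Σ scr(x,y)`, removing inter-subject
   weight differences.
2. **Hip localization** — the image is *weakened*,
   `dst(i,j) = min(scr(i,j), MeanVal × WeakenCoef)` with `MeanVal` the mean
   over the pressure area, to flatten bony pressure spikes, then
   cross-correlated with a bank of 36 signed **hip templates**: two reward
   discs of radius r₁ = 7 px separated by d = 12 px, a caudal disc (r₂ = 3,
   offset h = 3 px rearward), forward thigh rectangles (l = 9), and a
   negative "half-runway" penalty band of thickness c = 4 behind the discs
   (value k × distance, there is no pressure behind a seated body).  Four
   variants distribute the strong reward tier over the candidate
   high-pressure sites (both hips + caudal / left only / right only / caudal
   only), with reward sums equalized so every template carries the same
   correlation weight, each rasterized at 9 angles (−40°…40°, step 10°).
   The global argmax over all (template, position) pairs yields hip centers,
   body angle, and pressure-pattern variant at once.
3. **Parameter optimization** — exhaustive grid search of
   (v₂, v₃, k, WeakenCoef) minimizing the mean positioning deviation
   `J = Σᵢ (dist_lᵢ + dist_rᵢ) / (2N)` in pixels against marked hips
   (v₁ = 1 is the fixed reference; canonical optimum v₂ = 2, v₃ = 5,
   k = −0.3, WeakenCoef = 2.8).
4. **Posture classification** — three features per image: normalized
   pressure summed over discs at the left hip (r = 7), right hip (r = 7) and
   caudal vertebra (r = 3); z-scored (population σ) and classified into
   {upright, lean back, lean left, lean right} by one-vs-rest SVMs
   (polynomial / Gaussian / sigmoid kernels) under stratified 5-fold
   cross-validation.

Real seat-pressure recordings are not redistributable, so the package ships
a **synthetic scene generator** that paints annotated pressure images with
the same qualitative structure (ischial blobs with sharp bony cores, caudal
blob, thigh ridge, rigid rotation/translation, per-subject weight, sensor
noise and interference spikes), giving every stage exact ground truth.

## Worked example

```python
from sitmap import (SceneConfig, build_bank, generate_scene, locate_hips,
                    preprocess)
import math

bank = build_bank()                       # 36 templates (9 angles x 4 variants)
scene = generate_scene(SceneConfig(rotation_range_deg=(-30.0, -30.0),
                                   posture="upright", seed=11))
loc = locate_hips(preprocess(scene.image), bank)
print(loc.angle_deg, loc.left_hip, math.dist(loc.left_hip, scene.left_hip))
```

prints

```
true rotation:  -30 deg -> winning template angle: -30 deg (variant 1)
left hip:  predicted (12.00, 11.80), deviation 1.16 px
right hip: predicted (18.00, 22.20), deviation 1.16 px
```

i.e. the bank identified the body rotation exactly and placed both hip
centers within 1.16 px (≈ 1.3 cm) of the painted ground truth.  The
`examples/` directory has one short script per capability: scene
generation, preprocessing, localization, grid-search optimization, and
posture classification (on 192 default-noise synthetic images the
polynomial-kernel classifier reaches a mean 5-fold CV accuracy of 0.901).

A thin CLI wraps the same calls:

```bash
sitmap generate --out data/ --subjects 2 --n-per-cell 2 --seed 1
sitmap locate --annotations data/dataset.ann --out preds.ann
sitmap evaluate --annotations data/dataset.ann --report report.json
sitmap end-to-end --seed 1 --out report.json
```

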