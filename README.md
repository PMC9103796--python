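# hsskin

Hyperspectral photometric-stereo processing and pixel-wise lesion
classification for skin imaging.

Hand-held hyperspectral imagers can delineate skin lesions non-invasively,
but complex body sites (nose, eye corners, shoulders) leave strong surface
topography in the data.  One remedy is to *measure* the topography:
capture every wavelength under three known illumination directions,
invert the Lambertian shading model per pixel and band to get albedo and
surface normals, and integrate the normals into a relative height map.
The classifier then sees both the spectral and the geometric structure of
each pixel's neighborhood.

`hsskin` implements that pipeline end to end:

* **Sensor model** — bilinear Bayer demosaicing and the per-FPI-gap
  spectral calibration `S = C·R` / `R = C⁻¹·S` between RGB responses and
  radiance at the transmission-peak wavelengths.
* **Raw pipeline** — reflectance `(R−D)/(W−D)` against white/dark
  references, VIS+VNIR band combination into one 33-band cube
  (477–891 nm), per-wavelength photometric stereo
  `aN = L⁻¹·(r₀,r₁,r₂)`, Frankot–Chellappa depth integration
  `Z = Re 𝓕⁻¹[(−iωxP − iωyQ)/(ωx²+ωy²+ε)]`, and total-variation
  smoothing along the spectral axis.
* **Classifier** — a two-branch convolutional network (3-D convolutions
  over the 30×30×33 albedo window, 2-D over the 30×30 depth window,
  concatenated into dense layers, 3-way softmax: healthy / intradermal
  nevus / basal cell carcinoma), trained with Adam and categorical
  cross-entropy on slice-half sampled, oversampling-balanced,
  flip-augmented window sets.  The network engine is a compact, fully
  seeded numpy implementation.
* **Evaluation** — classification reports and confusion matrices, the
  slice-half experiment, and per-scene leave-one-out validation.
* **Synthetic scenes** — labeled measurements (Lambertian renders of
  known height fields with class-dependent albedo spectra, illumination
  profiles, dark level and sensor noise) providing exact ground truth for
  every stage; clinical data of this kind are not publicly available.

## Worked example

```python
import numpy as np
from hsskin import (
    make_dataset, process_measurement,
    run_slice_half_experiment, run_leave_one_out,
)
from hsskin.evaluate import prepare_scene_sets
from hsskin.classify import REDUCED_CONFIG

# 6 synthetic lesion scenes: lesions + healthy skin, exact ground truth
dataset = make_dataset(6, class_mix={"bcc": 0.5, "id_nevus": 0.5}, seed=1)

# raw pipeline on one measurement: 12 -> 6 -> 3 -> 2 -> 2 -> 2 images
result = process_measurement(dataset[0][0], log=print)
print(result.stack.values.shape)

# slice-half experiment: train on left halves, test on right halves
sets = prepare_scene_sets(dataset, n_lesion=50, n_healthy=20, seed=1)
sh = run_slice_half_experiment(sets, REDUCED_CONFIG, seed=1)
print(f"weighted accuracy {sh.report.weighted_recall:.3f} "
      f"on {sh.n_test_windows} test windows")
```

prints

```
stage radiance: 12 HS images
stage reflectance: 6 HS images
stage combine: 3 HS images
stage albedo and normal: 2 HS images
stage depth and albedo: 2 HS images
stage smoothening: 2 HS images
(256, 256, 34)
weighted accuracy 0.995 on 420 test windows
```

The stage log mirrors the processing-table bookkeeping (six radiance
cubes plus their white references in, one albedo cube and one depth map
out); the feature stack is 33 albedo bands plus the 575 nm depth channel;
and on these cleanly separable synthetic classes the slice-half model
classifies nearly every right-side test window correctly — a statement
about pipeline correctness, not clinical accuracy (see
`docs/methods.md`).

A command-line interface wraps the same stages:

```bash
hsskin simulate --seed 1 --out runs/sim        # synthetic measurements
hsskin process runs/sim/scene_000.npz --out runs/proc
hsskin train --reduced --seed 1 --out runs/model
hsskin loo   --reduced --seed 1 --out runs/loo
```

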