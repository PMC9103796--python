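# Methods

This note documents the models, conventions and numerical choices behind
`hsskin`, and what the synthetic experiments do and do not demonstrate.

## The imaging and inverse model

A measurement consists of six hyperspectral radiance cubes — three
illumination directions times two band groups (VIS, 17 bands 477–686 nm;
VNIR, 16 bands 700–891 nm) — plus white and dark reference cubes.
Reflectance is computed per band as

    R_refl = (R − D) / (W − D),

which removes both the additive dark level and the multiplicative
illumination profile.  The dark term is included even though the
illumination-ratio form alone would suffice under ideal conditions: with
a nonzero sensor dark level the plain ratio R/W is biased, and the
corrected form is what the reference-measurement procedure (dark frames
captured per cube) supports.

The skin is modeled as Lambertian.  With the three unit light directions
stacked as rows of the matrix L (elevation 60°, azimuths 90°, 330°, 210°
for the field center; rows (cos e cos φ, cos e sin φ, sin e)), each
pixel's three reflectances satisfy r = a·L·N, so

    v = L⁻¹ r,   a = ‖v‖,   N = v/‖v‖,

independently per wavelength.  Zero-length solutions (shadow/dead pixels)
are flagged and assigned N = (0,0,1), a = 0.

### Depth integration and sign conventions

Depth gradients are formed from normals as the printed ratio p = n₀/n₂,
q = n₁/n₂, with the z-component clamped at `clamp_nz = 0.01` so grazing
normals stay finite.  The Frankot–Chellappa step integrates (p, q) in the
Fourier domain:

    Z = Re IFFT[ (−i ωx P − i ωy Q) / (ωx² + ωy² + ε) ],

with the standard DFT angular-frequency grids (2πk/N, negative
frequencies in the upper half), ε = 1e−8 by default, and the DC quotient
forced to zero so Z has exactly zero mean (depth is only defined up to a
constant; ε alone would otherwise leak an arbitrary offset).

Two gradient sign conventions coexist in the literature.  For a surface
z(x, y) with normal ∝ (−z_x, −z_y, 1), the plain ratio gives p = −z_x and
the integral above returns the negated surface.  `gradients_from_normals`
therefore exposes both forms (`negate=False` is the plain ratio), and the
chained `reconstruct_surface` negates by default so the recovered height
map is upright (increasing toward the camera).  Coordinates: x = column
rightward, y = row downward, z toward the camera; all checks are
convention-consistent end to end.

The light matrix is exact only at the image center; with real (or
synthetically emulated) point-source LEDs the true directions vary across
the field and reconstruction error grows toward the borders.  The test
suite reproduces this qualitatively; the sampling margin that keeps
training pixels away from borders is partly motivated by it.

### Sensor model

The imager pairs a Fabry–Pérot interferometer with an RGB Bayer sensor;
one FPI air gap passes up to three wavelength peaks, mixed linearly into
the demosaiced RGB response: S = C·R with pixels as columns (S and R are
3×n, C is 3×3 per gap; this is the unique dimensionally consistent
arrangement).  C is fit by least squares over calibration exposures and
inverted as R = C⁻¹S, refused above a condition-number limit (default
1e6).  Gaps with fewer than three peaks leave all-zero rows in the
reference radiance; the corresponding unconstrained columns of C are
regularized to zero.  Demosaicing is classic bilinear interpolation
(normalized 3×3 convolution per channel, raw values kept at native
sites); the Bayer layout defaults to RGGB and is a parameter.

## Spectral smoothing

Albedo spectra are denoised with split-Bregman total variation along the
wavelength axis only — every pixel's 33-point spectrum is an independent
1-D problem, solved for all pixels simultaneously (pre-factored
tridiagonal system; penalty parameter μ = 2·weight, at most 30 Bregman
iterations or max-change < 1e−5).  The weight is a fidelity weight
(larger → closer to the input), default 10.  The solver is hand-written
because the off-the-shelf image TV denoisers smooth spatial axes and
cannot be restricted to the spectral direction.

## Machine-learning preprocessing

Per scene the classifier consumes a 34-channel stack: 33 smoothed albedo
bands plus the depth map of one visible band (575 nm by default, chosen
well inside the visible range) — using a single depth channel avoids 33
nearly redundant depth copies.  Channels are min–max normalized to [0, 1]
per scene after setting non-finite values to zero.

Each scene is split at the vertical line through the lesion mask's
horizontal centroid ("the middle of the lesion" made operational).
Training pixel centers are sampled without replacement strictly left of
the slice, test centers strictly right — 250 lesion + 100 healthy per
side at the study's full counts — all at least 15 px from the borders so
every 30×30×34 window fits.  Training windows are balanced by seeded
random over-sampling to the majority class and then quadrupled by
vertical, horizontal and double flips (the ×4 multiplier is the only
convention consistent with a four-fold augmented training count; flipped
copies carry provenance flags).  Balancing precedes augmentation.

The historical training-set figures 6160 (pre-balance) and 1190
(validation) are not derivable from 17 × (250+100) = 5950; the pipeline
exposes its own exact bookkeeping instead of reproducing those counts.

## Classifier

A two-branch convolutional network: the 30×30×33 albedo window enters a
3-D convolutional branch (treated as a single-channel volume), the
30×30 depth window a 2-D branch; each block is conv → LeakyReLU(0.1) →
max-pool, the flattened branch outputs are concatenated and passed
through dense layers to a 3-way softmax (0 healthy, 1 intradermal nevus,
2 basal cell carcinoma).  Training uses Adam at its standard defaults
with categorical cross-entropy, fully seeded (initialization, shuffling);
identical seeds give bit-identical runs.  An ablation switch drops the
depth branch.

The engine is a compact numpy implementation (im2col convolutions via
stride tricks + BLAS, analytic backprop verified against numerical
gradients).  Published architecture diagrams of this kind fix only the
block structure, so filter counts, kernels, dense widths, batch size and
epochs are this package's choices:

* default: 3-D branch (8, 3×3×7) and (16, 3×3×5) with 2×2×2 pools; 2-D
  branch (8, 3×3), (16, 3×3) with 2×2 pools; dense 64→16; batch 32;
  20 epochs;
* reduced (used by the experiments and the acceptance script): 4- and
  8-filter blocks with a stride-2 first convolution standing in for the
  first conv+pool pair, dense 32, batch 64, 8 epochs — sized to train in
  minutes on one CPU core.

## Synthetic study

Clinical data of this kind are not redistributable, so the generator
emulates the study conditions: 17 scenes (10 carcinoma, 7 nevus by
largest-remainder apportionment), each a 256×256 field of healthy skin
with one smooth-domed lesion (radius ≈ 41–54 px, height 4–8 px, jittered
center), rendered under the three 60°-elevation directions with a smooth
LED-like illumination profile, constant dark level 50 DN, signal scale
1000 DN and additive Gaussian noise of 0.005 reflectance units.  The
white reference stores the illumination profile itself (times the signal
scale, plus dark), so the reflectance correction cancels it exactly —
the convention that makes the noiseless forward model exactly invertible.

Class identity lives in smooth parametric albedo spectra (sums of
sigmoids/Gaussians in wavelength): healthy skin rises from green to NIR
with hemoglobin dips near 542/575 nm, the nevus template is darker
(melanin-like) and rises later, the carcinoma template is brighter with
shallower dips.  They are qualitative emulations, not digitizations of
any measured curves.  Each scene perturbs the templates with a smooth
seeded random curve (sd 0.01) far below the between-class separation.

A scene can be marked as carrying a *unique* lesion: its lesion borrows
the opposite lesion class's spectral shape plus a distinctive narrow
735 nm bump.  This is the synthetic analogue of a clinically unique
lesion (hair, scab, unusual pigmentation): a model that never saw the
scene has every reason to call the lesion the wrong class, while the
slice-half model learns the bump from the scene's own left half.

What passing these experiments shows — and does not show.  The synthetic
scenes obey the Lambertian model exactly, have no specular reflections,
registration error, focus variation, operator motion or class overlap,
and their class spectra are cleanly separable; near-perfect slice-half
accuracy here validates the pipeline's correctness and the experiment
harness, not clinical performance.  The leave-one-out drop on the unique
scene demonstrates the *mechanism* by which per-lesion uniqueness
degrades generalization, not its clinical magnitude.

## Experiment scales

The slice-half and leave-one-out experiments run at desk scale: 50 lesion
+ 20 healthy pixels per side per scene (the window-count bookkeeping
check still runs at the full 250+100, giving exactly 5950 test windows),
the reduced architecture above, and a 17-fold structural leave-one-out at
a deliberately tiny single-block configuration (its purpose is the
fold/provenance structure, not accuracy).  The unique-lesion fold is run
at the same reduced scale as the slice-half model so the pairing is fair.

## Known limitations

* Lambertian shading with a hard shadow clamp; no subsurface scattering,
  wavelength-dependent penetration or specularity.
* One global light matrix (field center); per-pixel light directions are
  deliberately out of scope.
* The Bayer/FPI sensor model and the scene generator are not coupled: the
  generator emits radiance cubes directly rather than raw mosaics.
* Normals are stored per wavelength (the depth map is wavelength-specific),
  which triples memory relative to a single normal field.
* The numpy network engine is single-threaded BLAS-bound; it is sized for
  the reduced experiments, not for the full default architecture on large
  training sets.
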