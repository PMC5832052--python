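# Methods

This note records the model, the tunable parameters, the synthetic
world the tests run on, and the numerical choices made where the design
was genuinely open. Every number quoted here is recomputed by the test
suite or the acceptance script; none is asserted from memory.

## The measurement model

The quantity of interest is the injured lung volume fraction
f = V_injured / V_lung of a single CT scan, and across two serial scans
the ratio f₁/f₂. The denominator V_lung deliberately includes the
injured voxels themselves — f is "the share of the lung that is
injured", which is only meaningful if injured tissue counts as lung.
This is why the segmentation stage fills interior holes (see below).

Volumes are voxel counts multiplied by the voxel volume (the product of
the three spacings, in mm³). No mesh integration is involved; the
marching-cubes export exists for visualisation and its enclosed volume
is only used as a consistency check (within 5% of the voxel volume for
smooth shapes).

## Stage-by-stage choices

### Anisotropic diffusion

Perona–Malik with exponential conduction g(d) = exp(−(d/κ)²), run
slice-wise in 2-D. Defaults: 10 iterations, κ = 50 HU, step 0.15.
κ sits between the noise scale (tens of HU) and the tissue contrasts
that must survive (parenchyma→injury ≈ 400 HU, parenchyma→body ≈
850 HU), so flat-region noise diffuses away while those edges are
essentially frozen. The explicit 4-neighbour scheme is stable for
step ≤ 0.25; the border uses zero-flux (reflective) conditions to avoid
edge darkening. Slice-wise rather than 3-D because the slice increment
(1.25 mm) is coarse relative to the pixel pitch (~0.7 mm) and the
segmentation criterion is seeded per slice.

### Region growing and hole filling

The acceptance band is |CT(p) − CT(seed)| < c·(CT_max − CT_min) with
c = 0.3 and the extremes taken over a 40×40-pixel window centred on the
seed on the seed's slice (clipped at image borders; a constant window
is rejected as degenerate). The inequality is strict. Growth itself is
volumetric and 26-connected (configurable to 6); a result covering more
than 90% of the volume raises a leak error.

A seed in aerated lung (≈ −850 HU) with a window spanning lung and soft
tissue yields an acceptance band of roughly ±300 HU, which *excludes*
consolidated injury (−450 HU) and vessels (+50 HU). Those structures
appear as interior holes of the grown aerated component, and a lung
mask that excluded them would make f meaningless (and could never reach
the high fractions seen in severe disease). `segment_both_lungs`
therefore fills holes by default — slice-wise 2-D first, then 3-D. The
2-D pass matters: vessels run through-plane and exit the lung at the
hilum, so in 3-D their lumen is open to the outside and would never
fill, while in every axial slice it is a closed hole. Whether the
criterion window is taken from the smoothed or the raw image is not
fixed by the procedure's description; the package uses the smoothed
image, which is the segmentation input.

### Texture features

Nine features per in-lung pixel from the 7×7 window, statistics over
valid (in-lung) pixels only with the divisor equal to their count — 49
for interior windows. Conventions chosen for reproducibility where the
definitions admit variants: SD is the population SD; skewness is
m₃/sd³ and kurtosis the excess m₄/sd⁴ − 3, both defined as 0 for
constant windows. The "original CT value" feature is the centre pixel's
HU value, keeping the feature count at exactly nine scalars.

The 3-D mean-CT correlation is read as the **product**
rco = (P̄ⁿ − P̄ⁿ⁻¹)(P̄ⁿ − P̄ⁿ⁺¹) of the two adjacent-slice mean
differences (a quotient reading exists behind
`slice_correlation_quotient`). The product is the reading consistent
with the feature's purpose: a partial-volume structure present on a
single slice makes both factors large *with the same sign*, giving a
large positive rco, while tissue continuing across slices gives values
near zero or negative; a quotient would be undefined whenever two
slices agree. On the first/last slice the only available neighbour is
used for both factors; a neighbour window containing no lung pixels
contributes a zero factor.

The whole-volume path (`feature_map`) computes the same features by
masked convolutions; HU values are shifted by the in-lung mean before
power sums are formed to avoid cancellation, and it matches the
per-window path to ~1e-7 relative (tested).

### Classifier

A 9→18→1 network with logistic hidden and output units, implemented on
scikit-learn's `MLPClassifier`, with per-feature z-scoring (training-set
statistics travel with the model — sigmoid units saturate on raw HU
scales). Training: Adam, cross-entropy, at most 5000 iterations, early
stopping with patience 50; the initial learning rate is 0.03 because
the sklearn default (10⁻³) stalls under early stopping on these small
standardized problems. sklearn cannot accept an external validation
set, so the train and validation partitions are concatenated and
`validation_fraction` is sized to reproduce the intended split. The
70/15/15 split is stratified and seeded. Decision threshold 0.5 by
default. Class imbalance is handled by stratification only.

Training labels generated from phantoms exclude vessel voxels from both
classes: a reader annotating injury avoids vessels, and the Hessian
filter is the designated mechanism for them. Features for training are
computed on the *smoothed* volume so that training and inference see
the same representation.

### Vessel filter

Frangi vesselness from `skimage.filters.frangi`, bright-on-dark
polarity, α = β = 0.5, structureness normalisation at half the maximum
Hessian norm per scale (the classic default), scales 1–4 mm converted
to voxel sigmas with the mean spacing. Responses are max-pooled over
scales and normalised to [0, 1] per volume; the map is computed inside
the dilated lung bounding box only. The segmentation threshold (default
0.15 of the peak response) is a configuration value justified by the
phantom benchmark: on a radius-2-voxel tube with the scale matched to
the radius, threshold 0.45 gives Dice ≥ 0.7 against the true tube.
Note that with the per-scale auto-normalisation the response is nearly
scale-invariant; the scale-selection behaviour (peak scale growing with
tube radius, at roughly half the radius) only appears with a fixed
normalisation constant, which is how the tests probe it.

### Post-processing and the ratio

Connected components below 30 voxels (26-connected) are removed —
"very small regions" is not quantified anywhere authoritative, so this
is a configurable default. The ratio is reported to 2 decimals in
outputs, full precision internally; a zero second-scan fraction raises
rather than returning an infinite or coerced ratio.

### Cohort statistics

Continuous survivor/nonsurvivor comparisons use Welch's t-test when
both groups pass a Shapiro screen at 0.05 and Mann–Whitney otherwise
(the selection rule is the package's own; only the menu of tests is
given by the source procedure). The gender table uses χ² without
continuity correction by default. All tests two-sided.

## The synthetic world

The phantom states: air −1000 HU; soft-tissue body 0 HU; two lung
ellipsoids at −850 HU; injured tissue at −450 HU textured as a Gaussian
random field (SD 60 HU, correlation length 2 voxels) — a pure offset
would leave the SD/skewness/kurtosis features uninformative, and GGO is
heterogeneous in reality; vessels +50 HU as through-plane tubes of
1.4-voxel radius; acquisition noise 30 HU (a realistic low-dose level);
grid 24×64×64 at (1.25, 0.7, 0.7) mm — a down-scaled axial acquisition
with clinical slice increment and pixel pitch. Optional through-plane
blurring emulates partial volume at lung boundaries.

Scan pairs share geometry; the follow-up injury is the admission region
grown outward by Euclidean-distance ordering to an exact voxel count,
inside the lung eroded by one voxel (so an aerated shell always
surrounds it and hole filling is well-posed) and avoiding vessels (so
truth fractions are exact). Truth fractions are therefore exact
rational numbers and any pipeline estimate can be scored without
ambiguity.

What a green test does **not** establish: the phantom has no airways,
no motion or beam-hardening artifacts, no left/right asymmetry in
injury patterns, sharp (not infiltrating) injury margins, and its
vessels are straight tubes. Classifier accuracy and the ±0.10
end-to-end ratio tolerance are statements about this world, not about
clinical scans. Clinical findings (survivor/nonsurvivor ratio
0.73 ± 0.17 vs 0.40 ± 0.14, decision bands at 0.3/0.8) are represented
only through the cohort generator's distributions and the power
properties tested on them.

## Known limitations

- DICOM series are not read directly (no DICOM library in the
  supported environment); NIfTI volumes and a plain-text slice-series
  format with rescale slope/intercept semantics cover the I/O contract.
- Per-pixel window classification spills into a ~3-pixel band around
  injury boundaries, biasing single-scan fractions upward (visible in
  the worked example: 0.398/0.903 estimated vs 0.354/0.781 truth). The
  bias largely cancels in the ratio, which is the prognostic output.
- Scans are analysed independently; no registration between admission
  and follow-up is attempted, and none is needed for the ratio.
- Vesselness uses the mean voxel spacing to convert mm scales to
  sigmas; strongly anisotropic grids would need resampling.
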