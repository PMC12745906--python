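# Methods

This note documents the models, numerical choices, and limitations behind
`sctforge`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`, not asserted from
elsewhere.

## Problem setting

Frameless SRS planning needs electron-density information (CT Hounsfield
units) co-registered with the MR volume used for target delineation. The
package synthesizes that CT from a single T1-contrast-like MR volume, then
restores the two pieces of the treatment geometry that an MR session cannot
capture: the thermoplastic immobilization mask and the head board. The
product, sCT_F, is what dose is computed on.

## Volumes, grids, and normalization

All volumes are `(z, y, x)` scalar grids with voxel-center coordinates
`origin + index·spacing` (mm), carried by a `Volume` dataclass with a `kind`
tag (HU, MR, NORM01, DOSE, LABEL). NIfTI is the only on-disk format; a JSON
sidecar carries the kind. NaN is the "not evaluated" marker (used by gamma
maps below the low-dose threshold); infinities are invalid everywhere.

Two normalization contracts feed the network:

* **MR → [0,1]**: division by the per-volume maximum. This is scale
  invariant (`a·v` and `v` normalize identically, `a>0`) and makes no
  assumption about MR units, which are arbitrary.
* **CT → [0,1]**: `raw = clip(HU + 1024, 0, 4095)`, output `raw/4095`.
  The +1024 offset is the standard CT storage convention (air at −1024 HU
  stored as 0); 4095 makes the unit interval attainable at the 12-bit
  ceiling of 3071 HU. The inverse (`HU = 4095·v − 1024`) composes to the
  identity on [−1024, 3071]; both directions are exposed because metrics
  are reported in HU.

Resampling uses `scipy.ndimage.map_coordinates` (linear for scalar volumes,
nearest for labels) with kind-specific background fill (HU → −1024, else 0).
Grids here are axis-aligned with diagonal affines, so one interpolation
backend serves resampling, spline warping, and rigid transforms identically.

## Head phantoms

`PhantomSpec` defines a family of ellipsoidal heads: an outer head ellipsoid
(per-subject jittered semi-axes, default ±8%) with a skull shell (default
6 mm, jittered ±15%) enclosing a brain interior. Defaults: 64×96×96 grid at
2 mm isotropic (tests and the acceptance script use coarser 4–6 mm grids;
sizes are stated where used). Tissue HU: air −1000, brain 40, skull
700 ± 60 per subject, i.i.d. Gaussian noise of 20 HU — values in the range
of adult head CT. The MR mapping is deliberately **not invertible from HU
alone**: brain is bright (800 a.u.) while skull (60 a.u.) and air (30 a.u.)
are both dark against 30 a.u. noise, mimicking the T1 bone/air ambiguity
that motivates the knowledge base. A smooth multiplicative field (±15%,
~8-voxel correlation length) stands in for coil shading. The template CT is
drawn from a disjoint seed namespace with 4× reduced noise (a template
would be denoised or averaged), so it never equals any subject.

What the phantoms do **not** emulate: real cranial anatomy (sinuses, soft
tissue classes, lesions), MR sequence physics, partial-volume behaviour at
1 mm resolution, or scanner artifacts. Passing tests therefore demonstrate
the machinery — contracts, geometry, learning dynamics, dosimetric
sensitivity — not clinical-grade synthesis accuracy; headline clinical
numbers from patient cohorts are out of reach of any phantom study and are
not claimed.

The mask phantom adds an anterior face shell and posterior support shell in
the band `[offset, offset + thickness)` of distance from the skin (defaults
6 and 2 mm; demo grids use 8 and 4 mm), a posterior board slab, and two
lateral spacer bars; device voxels never overwrite body voxels, and
generation fails if the geometry cannot be realised on the grid.

## The DRU

* **Input assembly.** Template slice correspondence uses fractional depth
  (`z/Z` matched), with edge replication at volume boundaries. The template
  context half-width `k` (default 2; `2k+2` input channels) keeps sample
  size tractable; the full-volume reading of the input contract is
  recovered by raising `k`.
* **Architecture.** Stem conv → per-level [residual blocks, 2×2 max-pool,
  channel-doubling conv] → bottleneck residual blocks → per-level
  [2×2 transposed conv, skip concatenation, merge conv, residual blocks] →
  linear 1×1 conv. Residual blocks are pre-activation
  (`y = x + conv(relu(conv(x)))`), so zeroed weights give the exact
  identity — a tested property. Odd slice sizes are symmetrically
  zero-padded to a multiple of `2^(depth−1)` and cropped after decoding.
  Convolutions are 2D over the slice stack treated as channels.
* **Training.** Defaults 150 epochs, batch 4, learning rate 0.01, and a 1/6
  validation split by subject mirror a clinical-scale recipe; tests and the
  acceptance script train 30 epochs on coarse grids. Loss is L1 on
  normalized slices (configurable to L2) — L1 matches the MAE evaluation
  criterion and is the common choice for sCT synthesis; the optimizer is
  Adam (a plain-SGD reading of a 0.01 learning rate is not stable for this
  task). Both were open design choices. Weights from the best validation
  epoch are retained. Everything is seeded and exactly reproducible (pure
  numpy, no threading nondeterminism); gradients are verified against
  finite differences in the tests.
* **Synthesis.** Slice-wise, order-independent; normalized outputs are
  clipped to [0,1] before denormalization and the clipped fraction is
  logged (`model.last_clip_fraction`).

The knowledge-base ablation (identical configuration, template channels
zeroed) is part of the test suite: with the bone/air-ambiguous MR mapping,
removing the template strictly raises held-out skull MAE in at least 2 of 3
seeds — on the pilot grids it holds in 3 of 3.

## Mask deformation and composition

* **Template extraction.** The masked-minus-bare CT difference thresholded
  at 100 HU defines the device support. The stored template carries the HU
  of the masked acquisition on that support (the raw difference at device
  voxels is device-minus-air, ~1150 HU, which is not a physical material
  value and would corrupt composition).
* **Spline.** 3D thin-plate-spline interpolation
  (`scipy.interpolate.RBFInterpolator`, affine polynomial term, zero
  smoothing): exact at anchors (≤1e-6 mm) and reproducing any affine
  displacement everywhere — both tested. Anchors come from a JSON file or
  are derived automatically on phantoms from six characteristic surface
  points (nose tip, lateral face edges, posterior neck, vertex, chin
  level), the regions where a thermoplastic shell contacts the patient.
* **Warping.** Backward (pull) warping: the field fitted on inverted anchor
  pairs is evaluated on the output grid and the template is sampled at
  `x + d(x)` — no holes, linear interpolation for HU, nearest for labels.
* **Board.** Least-squares rigid (Kabsch/Procrustes) registration of the
  four spacer-bar end landmarks onto their spline-deformed positions;
  closed-form, exact on noiseless landmarks, residual RMS reported. The
  "mask connection level" is operationalised as these spacer endpoints.
* **Composition.** Body voxels always keep sCT HU; devices fill background
  only (shells take precedence over the board on contested voxels);
  idempotent. A physicist's visual review is replaced by QA numbers:
  body-device overlap fraction and shell-skin distance statistics.

## Metrics

PSNR uses `MAX_I = 4096` on the 12-bit raw scale; since raw = HU + 1024,
HU differences equal raw differences, so MSE/RMSE/MAE can be computed
directly on HU and PSNR obeys
`PSNR = 20·log10(MAX_I) − 20·log10(RMSE)` exactly. Zero MSE is reported as
a flagged infinity, excluded from cohort means. SSIM uses the standard
three-component product with C1 = 0.01², C2 = 0.03² on unit-range
intensities; local statistics come from a 7×7 uniform window applied per
axial slice (2D, matching the slice-wise synthesis), computed on the full
volume and averaged over the region's voxels only — masked-window
alternatives bias edges. The window, its dimensionality, and the PSNR scale
were open choices and are configurable. When no label volume exists, bone
falls back to HU ≥ 150 inside BODY on the reference CT.

## Toy dose model and gamma

The dose surrogate attenuates each cardinal beam's ray intensity by
`exp(−∫ μ ds)` with `μ = μ_water·max(0, 1 + HU/1000)` and deposits it with
a Gaussian lateral (and 3σ longitudinal) profile about the beam axis
through each target. It is monotone — raising HU upstream can only lower
dose downstream — which is the property the sensitivity experiments need;
it is *not* a clinical dose engine (no scatter, buildup, or MLC modelling),
and beams are restricted to the six cardinal directions. `μ_water` defaults
to 0.005/mm (≈6 MV); the demo and acceptance configurations raise it to
0.02/mm so that coarse desk-scale grids resolve the dosimetric effect of HU
errors within the 3% criterion — a sensitivity choice of the experiment
design, recorded in the config.

Gamma: 3%/1 mm/15% threshold by default, globally normalized to the
reference maximum (the common clinical convention; local mode available),
reference fixed as the ground-truth distribution (asymmetry is asserted by
test), fully 3D. Sub-voxel sampling at DTA/10 within a 3×DTA search sphere;
offsets are visited in shells of increasing distance and voxels retire once
the spatial term alone exceeds their running minimum — an exact
acceleration, equivalent (|Δγ| ≤ 0.02 per voxel in the tests) to exhaustive
search. PTV mean-dose difference uses the convention that negative values
mean underdose on the evaluated distribution; ±5% is the usual secondary
acceptability bound. Cohort statistics report mean/SD, median/IQR, and
Pearson correlations (flagged undefined on constant series).

## Workflow scales

The demo configuration (5 train + 2 test subjects, 24×40×40 at 4 mm,
10 epochs) runs in well under a minute; the acceptance configuration
(20 + 2 subjects, 30 epochs) in about two minutes on one CPU. These sizes
were chosen as the smallest at which every studied effect (learning,
ablation, dosimetric sensitivity) is clearly resolved.

## Known limitations

* Phantom realism as above; absolute metric values on phantoms are not
  comparable to clinical cohorts.
* The numpy network trains at desk scale only; there is no GPU path, no
  augmentation, and no patch sampling.
* Template-to-subject correspondence is fractional-depth slice matching;
  no rigid pre-registration hook is wired in yet beyond resampling.
* DICOM ingestion, TPS-grade dose recalculation, and DVH metrics beyond the
  PTV mean are out of scope.
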