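# Methods

## Model

The package quantifies two geometric signatures of Alzheimer's-type change
on amyloid PET/CT. Amyloid deposition fills the cortex and smooths the
supra-threshold uptake region; neurodegeneration deepens sulci and roughens
the brain surface. Both are captured by comparing a region's surface area
with the surface area of the sphere of equal volume,
`A_sphere(V) = (36 pi)^(1/3) V^(2/3)`:

- `CASS = A_sphere(V_VOI) / A_VOI` on the amyloid volume of interest
  (dimensionless, in (0, 1] by the isoperimetric inequality up to
  discretization error);
- `BAI = A_brain / A_sphere(V_brain)` on the brain parenchyma mask
  (>= 1 up to discretization error);
- `shape feature = CASS x BAI`.

The VOI is every PET voxel at or above `k` times the non-zero SUV mean
(mean over strictly positive voxels; negative reconstruction noise is
clipped at load time so it cannot bias the mean). The comparison is
inclusive (`>=`), so a uniform image at `k = 1` yields a full rather than
empty mask. All supra-threshold voxels are kept by default — areas and
volumes of multiple connected components sum — with an optional
`min_component_voxels` filter (26-connectivity, treating the VOI as a
solid).

Thresholding at a multiple of the image's own mean makes the VOI exactly
invariant to global intensity rescaling, and both scores are dimensionless,
so the shape feature is invariant under uniform voxel-size rescaling.

### The `scale_sigma` convention

Reported CASS/BAI magnitudes in clinical use sometimes carry an arbitrary
unit factor (e.g. CASS in the thousands with a correspondingly tiny BAI):
for truly dimensionless ratios, the isoperimetric inequality forces
CASS <= 1 and BAI >= 1, yet such magnitude pairs multiply to a plausible
shape feature. The package therefore computes the dimensionless ratios and
exposes `scale_sigma` (default 1), which multiplies CASS and divides BAI,
purely to mimic magnitude conventions; the shape feature is algebraically
unaffected, which the tests verify to machine precision.

## Surface area and volume estimation

Volumes are voxel counts times the physical voxel volume, because the
scores pair "volume" with the segmented voxel set itself.

Surface areas are estimated two ways:

- **`mesh` (primary).** The mask is zero-padded (so the surface closes),
  anti-aliased with an isotropic Gaussian of 1 voxel standard deviation,
  and triangulated by marching cubes at the 0.5 level with spacing-aware
  vertex placement. The anti-aliasing is essential: the iso-surface of the
  raw binary field carries a staircase area bias of roughly +9% that does
  not vanish with resolution, whereas the anti-aliased estimate converges
  (measured relative error for digitized balls: ~10% at r = 5 voxels,
  ~2% at r = 10, ~0.5% at r = 20, <0.1% at r = 40). Below a feature
  radius of about 5 voxels the smoothing itself distorts the estimate,
  which bounds the documented discretization tolerance of +-0.05 on the
  isoperimetric limits of CASS and BAI. Masks whose anti-aliased field
  never reaches 0.5 (single voxels, single slices, sub-voxel-thin sheets)
  are rejected with a clear error rather than measured meaninglessly.
- **`voxel_faces` (oracle).** The count of voxel faces adjoining the
  outside, weighted by physical face area. It is exact for axis-aligned
  boxes (used as ground truth in tests) and a systematic overestimate for
  curved surfaces (→ 1.5x for spheres), so it brackets the mesh estimate
  from above. The bias factor depends on shape: it largely cancels between
  the VOI and brain terms for compact blobs but not for thin ribbons, so
  the two methods agree on group separation (both keep cohort AUC > 0.8)
  while individual rankings within near-tied cases can differ. The mesh
  method is the one to report.

Mesh-enclosed volume is available as a diagnostic
(`TriangleMesh.enclosed_volume`) but never feeds the scores.

## CT brain mask

The production method expects a parenchyma mask from a proper segmentation
(deep-learning or otherwise), supplied as a NIfTI file. For self-contained
operation a deliberately simple stub is included: a soft-tissue intensity
window (default 0-80 HU, excluding air at ~-1000 HU and bone well above
100 HU), largest 26-connected component, 3-D hole filling. Gray and white
matter are not distinguished — the combined parenchyma is what the surface
ratio needs.

`SUVr` is a plain mask-based stand-in for atlas-registered region ratios:
mean PET in the VOI over mean PET in the brain mask outside the VOI (whole
brain when the VOI covers it).

## Phantoms

Shapes are star-shaped solids `r(u) = R (1 + sum_i a_i s_i B_i(u) - mean) -
d tanh(S(u))` on the unit sphere: Gaussian bumps `B_i` (width 0.35 rad) on
random directions with random signs model broad lobulation; a family of 14
narrow bumps (width 0.18 rad) carves inward indentations whose depth `d`
(mm) models sulcal widening. The bump field is de-meaned over a fixed
642-point spherical quadrature so amplitude controls roughness at
near-constant volume (<3% drift across the tested amplitude range). A
10242-vertex reference mesh of the same radial function supplies
ground-truth area and volume independent of voxelization.

Defaults: 48x48x32 grid at (2, 2, 3.75) mm — the coarse slice thickness of
low-dose attenuation-correction CT, with assumed in-plane PET-like 2 mm
sampling — and base radius 26 mm, a scaled-down brain that keeps a
50-case cohort plus threshold sweep within seconds while leaving ~13
voxels of radius, enough for the mesh estimator's convergent regime.

PET emulation: `filled_smooth` places uptake 2.5 in the brain eroded by
3 mm over a background of 1.0 (the amyloid-positive pattern);
`cortical_ribbon` places uptake 2.0 on a peripheral shell (default 6 mm,
per-case 5.5-7.5 mm in cohorts) — the negative, white-matter-ribbon
pattern. A 4 mm FWHM Gaussian blur emulates scanner resolution and
additive Gaussian noise (sd 0.05) is clipped at zero. CT emulation places
the parenchyma at 40 HU inside a spherical 1000 HU shell with air (-1000
HU) elsewhere, so the stub's default window recovers the construction
exactly.

Because the phantom background is a uniform 1.0 rather than the mostly-zero
field of a real skull-stripped PET, the non-zero SUV mean sits near 1.07
and the clinical multiple `k = 6` would exceed the maximum uptake; phantom
cohorts are therefore quantified at `k = 1.5` (sweeps cover 1.2-1.8), while
the library default for real images remains `k = 6`. This is a property of
the phantom's intensity model, not of the method.

Cohorts draw per-case parameters from one master seed through an explicit
`SeedSequence([seed, stream])` splitting rule. The default effect (scale 1)
gives positives a filled-smooth pattern with probability 0.87 and deeper
sulci (mean 3.5 mm vs 1.0 mm, sd 0.8), negatives a ribbon pattern with
filled probability 0.04 — crossover rates mirroring typical visual-read
discordance, so group separation lands in a realistic AUC band (~0.9)
instead of being degenerate. Effect scale 0 makes the two groups
identically distributed (flagged as a null simulation) for type-I-error
calibration. MMSE-like integers (group means 22 vs 24.5, sd 3, clipped to
0-30) are included so rank-correlation machinery can be exercised.

What the phantoms do **not** emulate: real cortical topology and
gyral geometry, partial-volume effects beyond a single Gaussian PSF,
scanner physics (randoms, scatter, reconstruction artefacts), and
anatomical covariance between atrophy and uptake. Passing tests show the
estimators and statistics behave correctly on controlled geometry; they do
not certify clinical discrimination performance.

## Statistics

- **Mann-Whitney U** (two-sided): exact null distribution when
  `n1*n2 <= 400` and the pooled sample is tie-free; otherwise the normal
  approximation with tie-corrected variance and continuity correction.
  `U` counts pairs with the first group higher (half credit for ties).
- **ROC**: thresholds at every distinct score, positive call at
  `score >= t`; AUC by trapezoid (identical to `U/(n1 n2)`, asserted to
  machine precision); optimal cut-off maximizes Youden's J with ties
  broken toward higher specificity, reported as an observed score value.
  Higher score means predicted positive; polarity is never auto-flipped
  and AUC < 0.5 raises a warning. AUC standard errors and 95% CIs use the
  DeLong variance.
- **Correlated AUC comparison**: DeLong's placement-value test (verified
  against R's pROC to 9 decimals in the suite), with a stratified paired
  bootstrap retained as a validation oracle (decision agreement >= 95%
  at alpha = 0.05 across simulated cohorts).
- **Spearman**: Pearson correlation of mid-ranks; exact permutation
  p-value for n <= 8, t approximation otherwise; constant inputs are
  flagged, not raised.
- **Threshold sweep**: re-quantifies every case at each `k`; a `k` with
  empty (or un-meshable) VOIs in more than half the cases is flagged and
  excluded, never silently dropped; argmax ties are reported as a set.
- No multiple-testing correction is applied across the paired ROC
  comparisons; reports state each raw p.

## Numerical choices and degenerate inputs

- Anti-aliasing sigma 1 voxel; mask padding 4 voxels before iso-surfacing.
- Empty masks raise everywhere geometry is required; an empty VOI error
  reports the offending threshold and `k`.
- Threshold comparisons are inclusive; component filtering with
  `min_voxels <= 1` is the identity.
- All randomness is explicitly seeded (the CLI refuses to run simulations
  without a seed); derived seeds stay below 2^31.

## Problem sizes

The test suite and the acceptance script use 48x48x32 phantom grids,
50-case default cohorts, 50-phantom isoperimetric sweeps, 2000 score-level
null cohorts for Mann-Whitney calibration, and 500 cohorts x 2000
bootstrap replicates for the DeLong comparison — sizes chosen so the whole
battery completes in a few minutes on one core while keeping Monte-Carlo
error well inside the asserted bands. Image-level null calibration runs at
a reduced scale (60 cohorts of 8 vs 8 on 32x32x24 grids) on top of the
score-level calibration.

## Known limitations

- The mesh estimator is biased for features thinner than ~5 voxels; CASS
  of very thin ribbon VOIs is resolution-dependent (the ordering against
  smooth blobs is robust, the absolute value is not).
- The CT stub assumes calibrated HU-like intensities and a single
  connected parenchyma; it is not a segmentation method.
- The SUVr stand-in is not atlas-based; its absolute values are not
  comparable with published atlas-region SUVr.
- Phantom cohort effect sizes are qualitative by design; no claim is made
  that simulated AUCs estimate clinical ones.
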