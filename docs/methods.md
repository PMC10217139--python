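# Methods

## Scope and data model

All quantification operates on a `CalibratedStack`: one `(z, y, x)` integer
intensity grid per channel plus the voxel dimensions in µm. The default
calibration is the two-photon acquisition geometry (0.144 × 0.144 ×
0.988 µm), which makes lateral pixels ~7× finer than the z step; every
spatial operation is written to be anisotropy-aware. Intensities stay in
native 8- or 16-bit units from load to measurement — the object filters
include an absolute mean-intensity floor (60), so normalising at load
would silently change results.

## Histogram thresholding

Four global methods run on a 256-bin histogram (min–max mapped for 16-bit
data, matching the common macro environment):

- **Otsu** — maximise between-class variance ω₀ω₁(µ₀ − µ₁)².
- **Maximum entropy (Kapur)** — maximise the summed Shannon entropies of
  the two normalised class histograms.
- **Rényi entropy** — per-order threshold maximising
  (1 − ρ)⁻¹ log Σ(pᵢ/P)^ρ summed over the classes, for orders
  (0.5, 1, 2) with ρ = 1 the Shannon limit; the three sorted thresholds
  are blended by the classic three-threshold weighting rule (β weights
  chosen by whether neighbouring thresholds agree within 5 bins, blend
  coefficients from the cumulative mass at the extreme thresholds). When
  all three coincide the blend is the identity and is returned exactly.
- **Intermeans ("default" / IsoData variant)** — iterate
  t ← ⌊(mean of bins ≤ t + mean of bins > t)/2⌋ from the midpoint of the
  occupied range to its fixed point.

Conventions fixed throughout: the background class at candidate t is bins
0..t inclusive; foreground is *strictly greater* than t (for binned 16-bit
data the comparison is done in bin space so histogram and mask agree);
ties break to the smallest t; a histogram with one occupied bin raises a
degenerate-histogram error rather than guessing. Every method is tested
against an exhaustive search of its stated criterion.

## Soma volumetry

1. One whole-stack threshold (Rényi entropy by default) — a per-slice
   threshold could split a soma's identity across z.
2. Morphological opening with the discrete anisotropic ellipsoid
   {(x/5.5)² + (y/5.5)² + (z/2)² ≤ 1} (pixels). The opening is computed
   exactly via two Euclidean distance transforms with per-axis sampling
   1/r (a voxel survives erosion iff its scaled distance to background
   exceeds 1), which equals structuring-element erosion/dilation — the
   equivalence is tested — but runs in linear time on 10⁷-voxel stacks.
   The mask is padded with background first so the image border erodes,
   as the set definition requires.
3. Watershed splitting of touching somata: Euclidean distance transform in
   lateral-pixel units (z scaled by dz/dx), markers = h-maxima of the
   distance map (dynamic h = 1 lateral pixel by default; the ridge of a
   convex soma forms one connected plateau, so an isolated soma gets one
   marker), watershed on the inverted distance restricted to the mask.
   The union of labels always equals the input mask.
4. Per-object measurement: volume = voxel count × voxel volume; mean
   intensity on the *original* channel; flatness from the eigenvalues of
   the second-moment matrix of the voxel centres in µm. Semi-axes follow
   the uniform-ellipsoid relation Rₖ = √(5λₖ); flatness is R₂/R₃
   (configurable to R₁/R₃ — the shape vocabulary in the field is not
   unambiguous, and only the ratio matters, so the √5 constant cancels).
   A per-voxel box term (d²/12 per axis) regularises thin objects so
   flatness is finite and ≥ 1 even for a single voxel.
5. Filters, all inclusive on the kept side: volume ≥ 200 µm³
   (≈ 9763 voxels at the two-photon calibration), mean intensity ≥ 60,
   flatness ≤ 3.5. The intensity floor is what rejects bleed-through
   vessel fragments (which survive opening but are dim); the flatness cap
   rejects plate-like debris.

## Glia–vessel contact ratio

Both channels are smoothed with σ = 2 px laterally and σz = 2·dx/dz
axially (the stated sigma describes near-isotropic display pixels; a
literal 2-slice axial blur would mix ~4 µm of tissue). The crosstalk
subtraction max(glia − vessel, 0) is applied to the *smoothed, un-stretched*
channels: subtracting after both channels are stretched to the full native
range would force both foregrounds onto the same scale, cancelling any
voxel where glia and vessel are both bright and driving the overlap to
zero regardless of the true contact; in common native units only the bleed
copy (c × vessel, c < 1) cancels. (Both alternative orders remain
available via `ContactParams.subtract_stage`.) The contrast stretch then
saturates 0.7 % of voxels, split equally across the two intensity tails
(configurable to one-tailed); with saturation 0 the data pass through
untouched. Each channel is segmented with Otsu, and

contact % = 100 · |glia ∩ vessel| / |vessel|,

the 3-D voxelwise AND being identical to per-slice 2-D overlap aggregated
over z. An empty vessel mask is an error (undefined ratio); a glial
channel that is constant after subtraction yields an empty glia mask and
0 %.

## AQP4–vessel surface contact

The vessel (CD31) and AQP4 channels are smoothed with σ = 1 px and
segmented (Otsu for the dense vessel signal; maximum entropy for AQP4 —
perivascular AQP4 occupies well under 1 % of voxels, a regime where
variance-based thresholds collapse onto the background noise mode while
the entropy criterion stays on the bright tail). Two further defaults, both
configurable:

- voxels claimed by both segmentations are assigned to the vessel
  (`exclude_vessel_from_aqp4`), keeping the two objects disjoint as a
  surface-apposition measure presumes; without this the thresholded shell
  bleeds radially inward at vessel end-caps and inflates the contact
  percentage by up to ~30 % relative;
- a limit-of-detection guard (`min_contrast_sd` = 3): a global histogram
  threshold always produces *some* foreground, even on a signal-free
  channel, so unless the candidate foreground mean exceeds the background
  mean by 3 background SDs the AQP4 channel is declared empty.

The vessel *surface* is the set of mask voxels with at least one of their
6 face-neighbours outside the mask (image borders count as outside); the
contact surface is the subset within Chebyshev distance
`contact_distance` (default 1) of the AQP4 mask, and

surface contact % = 100 · |contact surface| / |surface|.

Voxel counts of boundary sets stand in for surface area: no meshing, and
the quantity compared across groups is a relative percentage, for which
the discretisation bias cancels. AQP4 volume is |mask| × voxel volume.

## 2-D immunopositive area

Maximum-intensity projection over z, one global threshold (intermeans for
Iba1, maximum entropy for GFAP, per the standard pairing), area =
positive pixels × dx·dy. The projection depth is recorded but not
enforced.

## Synthetic volumes and ground truth

The generator renders, at the two-photon calibration by default:

- **Vessels** — correlated random-walk centrelines biased along z (like
  penetrating cortical vessels), sampled every 0.3 µm, dilated to a 3 µm
  radius tube via a physical-unit distance transform. Default 2 vessels in
  a 128 × 256 × 256 stack give ~5 % vessel volume.
- **Somata** — axis-aligned ellipsoids with volumes drawn uniformly from
  400–1100 µm³ (the reported astrocyte/microglia regime, kept clear of the
  200 µm³ filter so segmentation shrinkage cannot drop borderline cells
  and bias the recovered mean) and axis ratios ≤ 1.4 (flatness well under
  the 3.5 cut). Centres are rejection-sampled away from vessels, from each
  other, and from the stack border so no soma is clipped.
- **Processes** — straight rays of radius 0.35 µm and length 8–15 µm from
  each soma centre; thin enough that the opening removes them.
- **Endfoot coverage** — a contiguous (wrapping) z-band of vessel voxels
  totalling `coverage_fraction` of the vessel, plus a 2-px outer sheath;
  glia and vessel masks genuinely overlap there, as the contact-ratio
  definition expects.
- **AQP4** — a perivascular shell outside the vessel over a z-band
  covering `aqp4_surface_fraction` of the vessel surface, one voxel deep
  axially (the ~1 µm z step already exceeds the layer thickness) and
  0.5 µm deep laterally (`aqp4_thickness_um`). A literal one-voxel sheet
  in every direction would be a 0.14 µm lateral film; its smoothed
  brightness splits into dim lateral walls versus bright axial caps, and
  entropy thresholds then intermittently lock between the two shell
  populations rather than between background and shell. Wall created by
  clipping a vessel at the axial border is never selected (the shell
  would have to sit outside the volume).
- **Signal model** — two-level rendering (background 10; glia 220, vessel
  90, AQP4 230 on the 8-bit scale), plus crosstalk c × vessel signal added
  to the glial channel (default c = 0.15), plus additive Gaussian noise
  (SD 15, i.e. SNR ≳ 5 for the dimmest channel with
  SNR = (foreground − background)/SD). Gaussian-only noise keeps the
  generator bit-reproducible across platforms; a Poisson branch would add
  detector realism the pipeline validation does not need.

Ground truth (per-cell volumes, contact ratio, surface-contact percent) is
always recomputed from the stored masks with the same definitions the
measurement modules use, so truth and measurement can never drift apart.
One seed drives all randomness; identical seeds give bit-identical stacks.

What the generator does *not* emulate: PSF anisotropy and diffraction
blur (structures have hard edges before noise), photobleaching, motion,
depth-dependent attenuation, autofluorescence, and vessels that branch.
Passing recovery tests therefore demonstrates that the pipeline logic is
correct and well-conditioned at realistic geometry, contrast and noise —
not that the specific published biological values would be reproduced
from raw animal data.

## Statistics

Shapiro–Wilk, ordinary one-way ANOVA, Tukey HSD and Welch t delegate to
scipy; repeated-measures one-way ANOVA partitions the within-subject
error directly (verified against pingouin) with no sphericity correction
by default. Degenerate designs are pinned down explicitly: identical
per-subject values give F = 0, p = 1; zero error with non-zero effect
gives p = 0. Percent changes are reported to one decimal. `build_report`
averages replicate images per subject before testing — subjects, not
fields of view, are the experimental unit.

## Problem sizes and tolerances

Recovery suites use ten seeds of 128 × 256 × 256 voxel stacks (≈ 8.4 M
voxels, ~37 × 37 × 126 µm), the generator defaults above, and assert mean
soma volume within ±10 % of truth and contact / surface-contact
percentages within ±20 % relative over coverage 0.05–0.30 and surface
fractions 0.05–0.40. Observed errors are far inside these bands (soma
≈ 1 %, contact ≤ 4 %, surface contact ≤ 7 %). The ANOVA type-I rate over
2000 null simulations is asserted within 5 % ± 2 %.

## Known limitations

- The Rényi blend weights follow the published three-threshold rule; other
  implementations differ in edge handling of the 5-bin agreement window.
- Surface area by boundary-voxel count is metrication-biased relative to a
  triangulated mesh; only relative comparisons should cross calibrations.
- The watershed dynamic h = 1 is conservative; heavily interdigitated
  somata may stay merged (they are then usually removed by the flatness
  filter rather than mis-measured).
- No deconvolution, registration or motion correction: stacks are assumed
  already aligned.
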