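# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Coordinate and intensity conventions

Arrays are indexed `(x, y, z[, t])` with axial slices along the third axis
and the slice index increasing rostrally; `+y` points posterior, so
"anterior to" a voxel means smaller y. Voxel indexing is 0-based; physical
coordinates are mm with the origin at the corner of voxel `(0, 0, 0)`, and
a point at `p` mm belongs to voxel `floor(p / voxel_size)` (half-open voxel
boundaries). Volumes are written as NIfTI with a diagonal affine carrying
the voxel size; gradient tables use the FSL bval/bvec convention;
streamlines are stored in TCK or TRK with mm (RAS) coordinates.

## Synthetic generators (`synthio`)

Every generator is a pure function of its spec, seed included; the noise
models follow magnitude-MR physics at the relevant SNRs — additive Gaussian
for the MT slab and BOLD series (high-SNR magnitude data), Rician for DWI
(two Gaussian quadrature channels before the magnitude).

**LC phantom.** Two tubes of radius 1.25 mm (the nucleus' nominal 2.5 mm
diameter) around left/right centerlines, rasterized by voxel-center
distance to the polyline, over a uniform pontine background. Defaults:
64×64×16 grid at 0.39×0.39×1.7 mm (MT-slab geometry), tube length 15 mm —
the textbook rostro-caudal extent; per-subject extent in vivo is variable,
so the length is a free parameter of the spec. `pons_mean` 100 a.u.,
`contrast_ratio` 1.15 (a typical LC/pons intensity ratio), `noise_sd` 5
a.u., i.e. image SNR 20 — a deliberately conservative floor for MT-TFL at
3 T; recovery only improves at realistic higher SNRs. The rasterized tube
is a capsule (rounded ends); for LC-like elongation (L ≫ r) its voxel count
stays within 20 % of the cylinder volume πr²L.

What the phantom does **not** emulate: partial-volume fading at the tube
boundary, the rostro-caudal intensity gradient of the real nucleus, field
inhomogeneity, registration error between slab and anatomy (registration is
outside this package). Passing recovery tests therefore demonstrate
correctness of the extraction arithmetic and its noise robustness, not
segmentation or registration performance on real data.

**Rater masks.** Manual delineation disagreement is simulated by flipping
up to `jitter_voxels` boundary voxels per axial slice (4-connected in-plane
boundary), independently for two "raters"; the Dice of the pair is
returned. Jitter that would empty an occupied slice is rejected rather than
silently tolerated.

**Oddball BOLD.** The ROI series is built on the volume grid:
`baseline + beta·z(task) + drifts + motion leakage + noise`, where
`z(task)` is the z-scored HRF-convolved target indicator. Because the GLM
z-scores its predictors, the injected `beta` is expressed in exactly the
units the fit reports (response per SD of the task regressor), making
noiseless recovery exact by construction and making "bias" well defined
under noise. Defaults mirror the acquisition the design assumes: 335
volumes at TR 1.7 s, 220 stimuli with 46 targets at ISI 2.5 s. Drift is a
2-cycle sinusoid (inside the span of the cycles-< 3 Fourier basis); motion
is a smooth random walk in 6 parameters.

**DWI.** Signals follow the single-tensor forward model
`S = S0·exp(−b·gᵀDg)` exactly (noiseless signals match the closed form to
machine precision); the default table is 64 uniform directions at
b = 1000 s/mm² interleaved with 7 b0 volumes. Crossing-fiber signal
generation is out of scope — per-fascicle ν/fvf maps are treated as inputs,
matching how a multi-compartment fingerprinting fit would supply them.

## LC contrast (`lc_contrast`)

* **Upsampling** is nearest-neighbor by default: it preserves intensity
  provenance, keeps masks binary, and makes the printed geometry exact
  (1 mm / 3 → 0.33 mm voxels; 15 × 0.33 mm = 4.95 mm reference side).
  Trilinear is available by flag. Phantom-based recovery studies run at the
  generator's native MT grid (factor 1): upsampling exists to protect
  in-plane resolution when resampling into an anatomical space, which is a
  registration concern outside this package.
* **Subdivision** operates on slice counts: caudal and rostral each take
  `floor(n/4)` slices, the medial subpart the remainder, so 25/50/25 holds
  exactly when 4 | n and the medial subpart (the majority by design)
  absorbs rounding. A physical-length split would differ only for strongly
  anisotropic voxels; slice counts are what a slice-wise protocol measures.
* **Peak selection** is the argmax within the mask per axial slice. Ties —
  which occur on flat plateaus such as saturated data or synthetic tubes —
  resolve to the tied voxel nearest the centroid of the tied set, then
  lexicographically smallest `(x, y)`. The centroid step makes the
  representative of a plateau its interior rather than its edge (an edge
  choice would leak background into the cross and bias the contrast down);
  for a two-voxel tie both are equidistant, so the rule reduces to the
  plain lexicographic tie-break. Fully deterministic.
* **The 5-voxel cross** is in-plane (center ± x, ± y) by default, because
  peak selection is per axial slice; a through-plane variant
  (center, ± x, ± z) is available by flag. A cross that would leave the
  volume is an error, never silently cropped.
* **Reference placement** defaults to `(peak_x, peak_y − offset)` with the
  anterior offset configurable (30 upsampled ≈ 0.13 mm voxels by default,
  i.e. ~4 mm; choose ~10 mm worth of voxels for native-resolution work).
  Explicit per-slice centers can be supplied to mimic manual placement.
  The region must lie fully inside the volume on every LC slice.
* The contrast is a pure intensity ratio, hence invariant to global
  intensity scaling; this is asserted by tests at 1e-12.

Measured behavior on phantoms (recomputed by `scripts/acceptance.py`):
noiseless recovery is exact; at SNR 20 the mean absolute error of the
whole-LC contrast over 100 seeds is ≈0.007. The residual error combines
the upward max-statistic bias of peak selection with the downward bias of
edge peaks whose cross touches background — both are properties of the
peak-cross protocol itself, not of this implementation.

## Oddball GLM (`oddball_glm`)

* **HRF**: difference of two gamma densities, peak delay 6 s, undershoot
  delay 16 s, unit dispersions, peak:undershoot ratio 6, sampled at TR and
  peak-normalized — the canonical double-gamma shape; all parameters are
  config-exposed because published "standard two-gamma" implementations
  differ in detail.
* **Convolution** is at the volume grid (onsets assigned to the containing
  volume); slice-level microtiming belongs to slice-timing correction,
  which is out of scope.
* **High-pass** follows the filter-by-regression reading of a Fourier
  cut-off of 3 cycles: sine+cosine pairs at 1 and 2 cycles per run enter as
  nuisance regressors, so any slower drift is absorbed by the fit rather
  than pre-subtracted. With the default layout the design has
  1 + 6 + 4 + 1 = 12 columns.
* **Z-transform** applies to every non-intercept column (population SD);
  z-scoring is idempotent to machine precision. Rank deficiency is an
  error that names the collinear columns.
* **Paradigm** pseudorandomization enforces at least `min_gap` standards
  between consecutive targets (default 1), the usual oddball constraint;
  the generator rejects infeasible target counts. The response window for
  accuracy scoring defaults to 2000 ms, inside the 2.5 s ISI.
* Inference uses the OLS t interval. Across 200 simulated runs at the
  generator defaults, beta bias is ≪5 % and empirical 95 % CI coverage sits
  in the 90–99 % band (the acceptance script reports the measured values).

## Tract microstructure (`tract_micro`)

* **Tensor fit**: plain (unweighted) log-linear least squares on
  measurements with b ≤ 1000 s/mm² — the tensor model is invalid at the
  high-b shells of a multi-shell scheme, so those are excluded by default
  (configurable). Non-positive magnitudes are clipped to the smallest
  positive float before the log. Eigenvalues are reported sorted
  descending, not clipped at zero: negative values are kept as a noise
  indicator and counted.
* **FA** uses the standard normalized eigenvalue-dispersion form
  `sqrt(3/2)·‖λ − MD‖/‖λ‖`; an all-zero tensor has undefined FA and is
  reported missing (NaN), as is wFVF where ν₁+ν₂ = 0 — a voxel without
  fascicles has no fiber volume fraction, and mapping it to 0 would bias
  tract means.
* **Dilation** "by one voxel in every direction" is 26-connectivity
  (3×3×3 structuring element); 6-connectivity is available by flag.
* **Voxelization** supersamples each streamline segment at a step of at
  most half the smallest voxel edge, with a power-of-two number of pieces
  per segment so sample points nest under step halving — refinement can add
  traversed voxels but never remove them.
* **Tract means** are voxel-unique and unweighted (each traversed voxel
  counts once regardless of how many streamlines cross it); a
  streamline-weighted mean would up-weight the dense tract core, which is
  a different statistic. Missing-valued voxels are excluded per metric and
  counted.

## Group statistics (`group_stats`)

* Models: `metric ~ predictor + age + sex + ASM count + epilepsy duration
  + benzodiazepine`, with the response group and the therapy duration
  fitted in separate models to avoid collinearity between them. Group and
  sex are binary-encoded; rows with any missing value are dropped listwise
  and the drop count is reported.
* BH-FDR is applied within configurable metric families (the subpart/side
  variants of one metric form a family in the demo); the family map must
  partition the outcome list. The implementation delegates to
  statsmodels' step-up procedure and is tested against a from-definition
  enumeration oracle for every list length up to 6.
* VIF is `1/(1 − R²)` of each predictor on the others; values ≥ 5 are
  flagged and perfect collinearity reports infinity rather than a large
  number.
* Mann–Whitney uses exact enumeration of all group assignments (midranks
  held fixed, two-sided p as twice the smaller tail, capped at 1) for
  pooled n ≤ 12, and the tie-corrected normal approximation with
  continuity correction above that. Fisher's exact test sums
  hypergeometric point probabilities at or below the observed table's.
  All tests are two-sided.
* Duty cycle: `(ON + 4 s)/(ON + OFF)`; the 4 s is the ramp time around
  each ON phase. A schedule is "rapid cycling" when OFF ≤ 66 s (1.1 min)
  while the duty cycle stays ≤ 0.5 — the published definition's "±" signs
  are read as "at most", and both thresholds are configurable because that
  reading is an interpretation. A duty cycle above 1 (OFF shorter than the
  ramp) is flagged invalid.

## Workbench

The demo generates `n` synthetic subjects (default 10, minimum 8 so the
6-predictor models remain estimable), first half non-responders, with
group effects injected on true contrast ratio (+0.05), oddball beta
(−0.5 SD units) and diffusion RD/fvf; covariates are drawn independently of
group so they act purely as noise dimensions. All randomness descends from
one master `SeedSequence`; NIfTI artifacts are written uncompressed so that
reruns are byte-identical. Demo problem sizes (48×48×12 phantom, 335-volume
series, 32×8×4 DWI grid, 20 streamlines) keep a full 10-subject run around
one second while leaving every stage non-trivial. The power simulation
uses the same machinery per replicate; at SNR 20 the contrast measurement
error (~0.007) is far below a 0.05 group difference, so detection is
essentially certain at any reasonable cohort size.

## Known limitations

* No registration, segmentation, fiber-orientation reconstruction or
  tractography: masks, aligned volumes and streamlines are inputs.
* The phantom's flat-intensity LC is a worst case for peak selection (all
  voxels tie) and a best case for the reference region (pure homogeneous
  background); real pontine reference regions can contain vessels or other
  structure the protocol handles by manual placement.
* The exact Mann–Whitney enumerates `C(n, n_a)` assignments and is
  intentionally capped at pooled n = 12.
* Tract means treat the scalar maps as registered to the streamline space;
  no interpolation is applied (nearest-voxel sampling at the traversed-voxel
  level), consistent with voxel-unique aggregation.
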