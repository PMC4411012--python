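# Methods

This note documents the models, numerical choices and limitations behind
`arraytomo`. It describes what the code computes and why; every number
quoted here is produced by the test suite or `scripts/acceptance.py` at
run time.

## Volume model and addressing

A data volume is an ordered set of channels on a common anisotropic
grid. The default voxel is 100×100×70 nm: in-plane sampling at the
effective post-deconvolution resolution of AT imaging, axial sampling
equal to the physical section thickness. Arrays are indexed
`data[x, y, z]`; one z index is one physical ultrathin section.

Cutout ranges are 0-based and half-open, so a range `(700, 1700)` has
width 1000 — this convention makes the widths of published cutout URLs
equal `max − min`, and it composes (a cutout of a cutout equals the
cutout of the composed range). Physical volumes in µm³ are rounded to
the nearest integer, half away from zero; this reproduces all eight
checkable published data-volume sizes exactly from their printed voxel
counts. The half-resolution level (`resolution=1`) is a display mipmap:
2×2 mean pooling in x and y only, z untouched, odd trailing rows/columns
dropped. Composites min–max scale each channel independently, multiply
by the slot color (cyan, yellow, magenta, red, green, blue, in listed
order, `"0"` consuming a slot), sum, and clip — so overlapping channels
blend additively.

Intensities are stored as unsigned 16-bit in containers; all metric
computations run in double precision.

## Synthetic scenes

The generator's purpose is to produce volumes with the statistical
structure the downstream analyses assume, with complete ground truth.
It is not a model of optics or of any particular dataset.

* **Synapse loci** are a homogeneous Poisson process in the neuropil
  (the volume minus planted somata): the count is Poisson with mean
  density × neuropil volume, positions uniform with rejection inside
  somata. The default density is 1.0 locus/µm³, the textbook figure for
  cortical neuropil.
* **Channels** render an anisotropic 3D Gaussian punctum at each locus
  they participate in (participation probability per channel). Default
  widths σ = 150×150×100 nm approximate diffraction-limited puncta.
  Postsynaptic-style channels displace each punctum from its locus by a
  vector of random direction and length ~N(150 nm, 30 nm) — apposed
  pre/postsynaptic compartments are separated by roughly the synaptic
  cleft plus half the compartment sizes — which is what broadens their
  cross-channel correlation peaks relative to co-compartment pairs.
  Rendering truncates each Gaussian at 4σ (99.89% of 3D mass);
  amplitude is the peak value before noise, default 20 000 a.u. on the
  16-bit scale.
* **Nuclei** are Gaussian balls (σ = radius/2) in DAPI-like channels;
  **somata** are spheres that exclude synapse loci, so Synapsin-style
  channels are dark inside them while remaining dense outside.
* **Noise** is additive Gaussian (default σ 2 000 a.u., i.e. peak SNR 10
  at the default amplitude) plus optional Poisson shot noise, applied
  last, clipped to [0, 65535].
* **Determinism:** one `numpy` Generator seeded from the scene seed
  drives every draw in a fixed order; identical specs give bit-identical
  volumes and truth tables.

What the generator does **not** emulate: real PSF blurring and
z-bleed-through beyond the punctum model, barrel/septa cytoarchitecture,
neurite morphology, staining variability across rounds beyond the
participation model, or section-to-section elastic distortion. Passing
tests therefore demonstrate correctness of the computations under the
stated statistical assumptions, not performance on any real dataset.

Session misregistration resamples each section of the selected channels
under one rigid transform plus independent per-section translation
jitter (shared across the session's channels, which are imaged
simultaneously); the planted transform and jitter table are recorded.
Mosaic tiling covers a section with tiles at nominal stride
`tile × (1 − overlap)`, evenly redistributed so the last tile ends flush
with the edge (e.g. a 1000 px section with 600 px tiles at 20% overlap
tiles at origins 0 and 400).

## Preprocessing

Rolling-ball background subtraction uses the classical non-flat ball
kernel (a ball of the given radius rolled under the intensity surface;
equivalently grayscale opening with a spherical-cap structuring
element), radius 20 px by default. The estimated background never
exceeds the image, so outputs are non-negative and bounded by the input.
Because the kernel is non-flat, positive homogeneity and idempotence
hold only approximately (within ~10% on rough texture, ~1% on smooth
puncta); exact versions of those identities would require a flat
element, which is not the classical filter.

Deconvolution is Richardson–Lucy (the standard choice for fluorescence;
the algorithm used for the original volumes is not specified beyond
"empirical PSFs"), default 20 iterations, with reflective edge padding
of half the kernel size. RL preserves non-negativity; flux of a fully
interior source is conserved to ≲1% (asserted in tests). A unit-impulse
PSF is an exact identity. The PSF may be measured (loaded from
TIFF/array) or a Gaussian model.

## Registration

All in-plane motion is modeled as rigid (rotation + translation). The
published reconstructions additionally used elastic per-section
deformation for fine alignment; that is deliberately out of scope here
and is the main known limitation for real ribbons with tissue
distortion.

* **Pairwise tile offsets** maximize the Pearson correlation of the
  overlap over integer shifts within a search radius of the nominal
  stage offset; the peak correlation is the confidence.
* **Global stitching** solves the least-squares consistency problem over
  pairwise offset constraints with tile 0 pinned (exactly consistent
  inputs are recovered exactly); fusion uses linear feathering (weights
  taper to zero at tile borders).
* **Session registration** detects bright LoG blobs (nuclei) in the
  DAPI sections of both sessions, refines them to subpixel by local
  centroid, proposes correspondences by mutual nearest neighbour after a
  coarse phase-correlation shift, and fits a rigid transform by RANSAC
  (2-point minimal samples, default 1000 iterations, 2 px inlier
  tolerance, seeded) refit on the inliers by orthogonal Procrustes. The
  recovered transform applies identically to every channel of the
  session. Blob correspondence replaces gradient-based keypoints because
  nuclei are intrinsically blob-like and it keeps the implementation
  self-contained. Measured recovery at 10% noise over 50 seeds: ≤0.25 px
  and ≤0.23°, against a 0.5 px / 0.5° contract.
* **Stack alignment** registers each section to its predecessor by
  subpixel phase correlation (adjacent 70 nm sections of a dense
  synaptic stain share most of their puncta) and chains the pairwise
  transforms outward from the **middle** anchor section, halving drift
  accumulation. Planted 2 px RMS jitter is reduced to ~0.1–0.2 px RMS.
  On an already-aligned stack the chain is not exactly identity:
  adjacent sections carry genuinely different content, so each pairwise
  estimate wanders by a few hundredths of a pixel and the chain
  accumulates a little of it (bounded at 0.25 px in tests).

Transforms rotate about the image center by convention; composition and
inversion are center-independent and round-trip to identity within
1e-9.

## Colocalization

For channels A and B, `r(du, dv)` is the Pearson correlation of
A(x, y) against B(x + du, y + dv) over their overlap, computed per
section and averaged over sections with equal weight (first 10 sections
by default, matching the averaging depth used for the published
analysis). Swapping channels reflects the map through the origin
exactly; correlations are invariant to positive affine intensity
rescaling.

The peak summary takes the map maximum, a background level equal to the
mean correlation over the outer two shift-radii of the window (the
published analysis says only "average background correlation"), and a
half-max threshold midway between them. The half-max contour is traced
by marching squares with linear interpolation — hence fractional px²
areas — and only the closed contour containing the peak is measured
(shoelace area; diameter of the equal-area circle). A single hot cell
over a zero background yields the interpolation diamond of area exactly
0.5 px².

The published per-antibody cross-correlation table reports every
self-correlation peak as a constant well below 1, implying a
normalization that is not described; Pearson correlation is used here
(self-peaks are exactly 1) and no numeric value of that table is treated
as a target.

## Stain consistency

Percent consistent is a Jaccard index ×100 over the above-threshold
pixel sets of two rounds; the threshold (default 1 000 a.u.) is strict
(`>`), and an empty union returns 0 with a warning. The background
variant applies the same formula to the complements. The 180° rotation
of the later round destroys spatial correspondence while preserving all
marginal statistics, so the rotated metrics estimate chance levels; for
independent sparse masks with foreground fractions p_A, p_B the expected
rotated percent is 100·p_A·p_B/(p_A + p_B − p_A·p_B), which the tests
verify by simulation. Whether the original analysis thresholded before
or after background subtraction is unspecified; the metrics here apply
to whatever images they are given.

## Puncta segmentation

1. **Seeds** are strict local maxima within a spherical neighbourhood of
   3 voxels radius (all axes; the 100 vs 70 nm anisotropy is ignored for
   the neighbourhood, configurable) above a detection floor. Exact
   plateaus resolve to the lowest linear index.
2. **Detection floor** defaults to background median + 3 robust SD,
   where the robust SD is the larger of 1.4826×MAD and the
   84.1th−50th percentile spread. The two estimators agree on Gaussian
   backgrounds; the percentile spread keeps the floor honest when the
   background is clipped at zero (a zero-heavy histogram collapses the
   MAD to zero), and both vanish on noiseless, mostly-empty volumes.
3. **Watershed** on the inverted intensity, restricted to suprathreshold
   voxels, partitions the foreground among the seeds.
4. **Gaussian model** per region by intensity-weighted moments (mean and
   full covariance), with the detection floor subtracted from the
   weights so a uniform suprathreshold pedestal does not inflate the
   widths. Moments rather than iterative least squares: deterministic,
   fast, and accurate to <5% per-axis width at the tested SNR; the 4σ
   render truncation biases widths by <0.1%.
5. **Mask** = region voxels within Mahalanobis radius 2 of the model
   ("two standard deviations" in the width convention adopted here).
   For a 3D Gaussian this encloses P(χ²₃ ≤ 4) ≈ 73.9% of the mass — not
   90% (no standard 3D width convention gives 90%; the ±2σ box gives
   ≈86.9%). The tests pin the within-mask intensity to the χ² value at
   2% tolerance, using punctum widths of ≥2 voxels per axis so that
   voxel-center sampling resolves the elliptical mask boundary.

Reported per punctum: centroid (voxels and µm), per-axis σ, mask voxel
count, within-mask intensity sum (the "punctum intensity" used for
density/intensity statistics), peak intensity, and the analytic model
integral amplitude·(2π)^{3/2}·σxσyσz. Regions with fewer than 4
positive-weight voxels are rejected and counted. On the standard
benchmark (50 well-separated puncta at peak SNR 10, 10 seeds) recall and
precision are 1.0 and the worst centroid error ≈0.25 voxel. At
densities ≥1–2 puncta/µm³, near-neighbour puncta within the maxima
radius occasionally merge, giving a few-percent (at 0.5/µm³) to ~10–15%
(at 2/µm³) count deficit; paired-layer comparisons are insensitive to
this because both ROIs lose the same fraction.

## Neuropil and density statistics

The neuropil mask binarizes the Synapsin channel (Otsu by default),
dilates with an ellipsoidal element (default radii 5×5×4 voxels ≈
500×500×280 nm; implemented via a distance transform in radius-scaled
coordinates) and fills holes smaller than a configurable voxel count
(default 2000 — inter-punctum gaps, not somata). The default radii
bridge inter-punctum gaps only partially at 1 locus/µm³; analyses that
need near-complete neuropil coverage (e.g. the unbiasedness benchmark)
use larger radii (10–14 voxels), and coverage cancels in paired
comparisons because the same estimator runs on both ROIs.

A punctum belongs to an ROI when its centroid voxel lies in
ROI ∩ neuropil; density is count per µm³ of that intersection, and the
intensity summary is the median within-mask punctum intensity. The
exact Wilcoxon signed-rank test drops zero differences, midranks ties,
and computes the two-sided p from the exact distribution of W via
dynamic programming on the doubled ranks for n ≤ 25 (normal
approximation with continuity correction above), combining tails as
2·min(P(W≤w), P(W≥w)) capped at 1. Two-sided is adopted because the
published small-n p-values (0.0313, 0.0156 at n = 7) equal exact
two-sided tails. Cross-ribbon comparisons average same-class ROIs
within each ribbon (arithmetic mean), form one pair per ribbon, and
report the median of the per-ribbon percent differences
100·(g₁−g₂)/g₁.

## Benchmark problem sizes

The recovery benchmarks are sized to exercise each contract at
convincing statistics: session registration on 256² single-section
scenes with 40 nuclei over 50 seeds; stack alignment on a 128²×20
Synapsin stack; segmentation on 50 puncta in 96²×24 volumes over 10
seeds; the power study on 100 cohorts of 7 ribbons, each ROI a 64²×12
volume (~100 µm³, ~100–200 vGluT2 puncta) — large enough that a planted
2× density ratio puts all 7 ribbon differences on the same side in
essentially every cohort, while null cohorts (ratio 1) center on zero
difference.

## Known limitations

* Rigid-only alignment; no elastic section deformation.
* The cross-correlation normalization of the published per-antibody
  table is unknown; absolute values are not comparable, structure is.
* Moment-based Gaussian fits assume one dominant punctum per watershed
  region; heavily overlapping puncta merge rather than split.
* The synthetic noise model (Gaussian + optional Poisson) has no fixed
  pattern noise, bleaching, or section-loss artifacts.
* Numeric channel tokens are positional (1-based) per volume, as in the
  published access scheme; they are not stable across volumes.
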