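# Methods

`lungcad` characterises a segmented pulmonary nodule from a single CT volume
and classifies it as benign or malignant.  The biological premise is that a
malignant nodule's rapid growth produces (i) heterogeneous interior texture
(irregular Hounsfield-unit structure) and (ii) an irregular, spiculated or
lobulated outer margin, while benign nodules stay homogeneous and nearly
spherical.  Three appearance descriptors and three shape descriptors measure
these two signatures; each feeds a stacked-autoencoder classifier whose
malignancy probability is fused by a final network.

## Geometry and preprocessing

Volumes are axis-aligned grids of HU values indexed `(x, y, z)`; physical
position of a voxel is `origin + index * spacing` (no direction cosines).  A
40 mm cubic volume of interest (VOI) is cut around the nodule centroid and
resampled to 1 mm isotropic voxels by trilinear interpolation; out-of-volume
regions are filled with −1000 HU (air).  The multi-view descriptors share one
plane family: a pencil of planes containing the z axis and the centroid,
rotated about z by `k·180°/V` (antipodal planes coincide).  Plane slices are
sampled bilinearly; mask slices are clipped to [0, 1] and thresholded at 0.5.

## Appearance descriptors

**Multi-view analytical LBP (ALBP).**  The classic LBP code
`Σ 2^(i−1) f(g_i − c)`, `f(x)=1 iff x≥0`, thresholds a pixel's circular
neighbours at the centre value and is noise-brittle.  The analytical variant
replaces raw neighbours with per-level statistics: for levels `R = 1..3` the
circle of radius R is resampled (`full_n`: 8R points; `single_n`: 8;
`average_n`: 8R points averaged over 8 contiguous arcs — the default), each
level is summarised by median/mean/population-sd/min/max, and each statistic
is thresholded at its own mean over levels, yielding five 3-bit code maps.
Per view, per statistic, the code histogram over the nodule cross-section is
normalised to sum 1; concatenation over 5 views gives 5·5·8 = 200 features.
Codes are invariant to global gray shifts.  A tolerance of `1e−9·max|g|` is
built into the threshold so that bilinear round-off on flat regions cannot
flip a bit.  Histograms are restricted to the mask cross-section so the
feature reflects nodule, not background; per-view histograms are concatenated
rather than summed to preserve view information.

**Fast 3D HOG.**  Central-difference partial-derivative volumes (one-sided at
faces) are cumulatively summed into integral gradient volumes, making the
mean gradient of any box an O(1) eight-corner inclusion–exclusion read.  The
VOI is edge-padded to 45³ and tiled into 5³ blocks of 3³-voxel cells; each
cell's mean gradient casts one weighted vote onto the vertex directions of a
platonic solid (default dodecahedron, 20 bins, full binning).  Votes:
`C = V·N/|N|`, subtract the adjacency threshold (the largest dot product
between two distinct bin directions), clamp negatives, *keep only the three
largest components* — the threshold alone provably leaves up to five positive
components near face centres, so the nearest-3 constraint is enforced
explicitly — then rescale to carry `|N|`.  Cell votes are summed per block
and each block histogram is L2-normalised (ε = 1e−12), giving 125·20 = 2500
features.  Voting is per cell, not per voxel: the integral-volume machinery
exists precisely to replace voxelwise work with one box query per cell.

**MGRF Gibbs energy.**  A translation-invariant Markov–Gibbs random field over
Q = 32 quantised levels (1st–99th percentile HU range of the benign training
nodules) models normal texture, `P(g) ∝ exp(−E(g))`.  Clique families: the 13
symmetric pairwise offsets of the 26-neighbourhood, configuration = ordered
level pair, independent-field reference 1/Q²; plus a 7-voxel star (centre + 6
face neighbours), configuration = (centre level, number of neighbours within
±1 level), reference from the exact uniform binomial.  Potentials are the
analytic first approximation of the MLE: `λ·(F_emp − F_ref)` with λ = 1,
pooled over benign training nodules.  The per-voxel energy is minus the sum
of potentials of all cliques containing the voxel (zero outside the mask);
the descriptor is the normalised histogram of in-mask energies (default 1000
bins) over a fixed range calibrated to the 0.5–99.5 energy percentiles of the
training set.  The partition function is never needed.  Energy polarity is
not hard-coded; the histogram feeds the classifier either way.

**PSCSS (multi-view peripheral sum curvature scale space).**  For each view
the binary cross-section is smoothed at Gaussian scale σ, Canny edges are
traced into the longest closed 8-connected contour, re-oriented
counter-clockwise and resampled to uniform 1-px arc length (pixel chains mix
1 and √2 steps; index-based derivatives on that parametrisation alone flip
curvature signs).  Curvature uses symmetric differences at a 15-px gap with
wrap-around; reversal points are curvature-sign changes (zero-curvature runs
carry the sign).  The descriptor is the per-σ sum of reversal counts over 5
views.  Views are sampled at 0.25 mm/px so the 15-px gap spans ≈1.9 mm of
contour on desk-scale nodules.  The σ grid {8, 12, 16, 24, 32} px starts near
the curvature-stencil scale: below the voxel scale edges show only the
interpolation staircase of the binary mask, and below the ±gap stencil span
(30 px ≈ 7.5 mm of arc) clusters of spicules narrower than the stencil can
*gain* resolved undulations under smoothing, so counts are reliably
non-increasing in σ only from the stencil scale upward.

## Shape descriptors

**Spherical harmonics (SPHARM).**  The mask boundary is iso-surfaced by
marching cubes at level 0.5.  General meshing (`mesh_from_mask`) applies a
0.6-voxel Gaussian pre-smooth — raw marching cubes on 0/1 data inflates the
area of a ball by ≈9% through staircase facets — but the SPHARM descriptor
meshes the *raw* mask: the pre-smooth erodes one-voxel spicules, which are
exactly the high-order content this descriptor measures.  Vertices are
centred, projected to the unit sphere and
relaxed by attraction–repulsion: each vertex moves toward its mesh-neighbour
centroid (weight 0.1) and away from nearby non-neighbours (inverse-square,
truncated at twice the mean spherical edge length, weight 0.01), renormalised
every step; up to 500 iterations or max displacement < 1e−6.  Stronger steps
(e.g. 0.5/0.1) make the spherical Laplacian iteration collapse with mass
face fold-over; the chosen constants reduce the neighbour-distance spread
monotonically with no flips.  The three coordinate functions are fitted with
a real orthonormal SH basis by iterative residual fitting: order blocks
low-to-high, each least-squares against the residual of lower orders.  The
descriptor entry at order L is the RMS vertex distance of the order-≤L
reconstruction divided by the mean radius (RMS, not mean distance, because
RMS is the quantity the least squares minimises, making the curve
non-increasing by construction); orders 1..70.  For speed the fit uses a
deterministic even-strided subset of ≤1200 vertices and the full SH table
from `scipy.special.sph_harm_y_all`.

**Geometric features.**  Seven morphology scalars from the mask: voxel
volume, convex volume, equivalent-sphere diameter, iso-surface area (with the
same 0.6-voxel pre-smooth), solidity, principal axis length (skimage's
equivalent-ellipsoid `axis_major_length`), extent (volume / axis-aligned
bounding box).  Convex volume rasterises the hull of voxel *centres*
(`convex_hull_image(offset_coordinates=False)`): the corner-offset default
adds a one-voxel shell that drags the solidity of a convex digital ball to
0.91, whereas the centre convention gives exactly 1.

## Classification

Stage 1, per descriptor: three autoencoder layers whose widths shrink to 2/3
of their input (`ceil(2d/3)`, floor 2) — "reduces the dimensionality by one
third" read as reduce *by* a third; reduce *to* a third is available as a
config switch.  Plain (non-denoising) autoencoders, sigmoid encoders, linear
decoders, MSE loss, full-batch Adam, 200 greedy pretraining epochs per layer,
then a 2-class softmax head fine-tuned end-to-end for 200 epochs
(cross-entropy).  Features are z-scored per column; zero-variance columns are
neutralised.  Stage 2: the six malignancy probabilities feed one hidden
autoencoder layer of width 4 plus softmax, trained the same way.  Everything
is float32 internally and bit-for-bit reproducible given (data, config,
seed).  Evaluation: accuracy, sensitivity, specificity, precision (percent,
threshold 0.5, malignant positive) and trapezoidal ROC AUC; cohorts are split
70/30 with stratification.

## Synthetic phantoms

The generator supplies the study conditions for every test: 40 mm VOIs at
1 mm spacing, nodule mean −50 HU on a −850 HU background (both with 10 HU
background noise so the background carries no class signal).

* Benign: axis-aligned ellipsoid with semi-axis eccentricity ≤ 8%, interior
  white noise of 5–15 HU.
* Malignant: star-shaped boundary `r(u) = R(1 + A·Σ_j exp(κ(u·d_j − 1)))` —
  a corona of narrow von-Mises–Fisher spicules (κ = 60, i.e. ≈11° half-width)
  with relative amplitude A ∈ (0.5, 0.7) and 48–64 spicules on a randomly
  rotated Fibonacci lattice (lattice spacing guarantees the spicules stay
  distinct boundary maxima); interior is a Gaussian random field smoothed to
  a 2–4 mm correlation length and scaled to 30–60 HU.
* Radii span 7–12 mm; every mask stays strictly inside the VOI (boundary
  radius clipped at 19 mm).

The spicule regime was chosen to satisfy the shape contrasts jointly: many
narrow tall spicules make the mask clearly non-convex (solidity ≤ 0.9 from
amplitude 0.3 upward, ≈0.7–0.8 at defaults) and keep the boundary's RMS
radial deviation above a tenth of the mean radius, so spiculated phantoms
need SH order ≈8–11 to reach a 0.1 relative error versus order 1 for smooth
ones; broad lobes — the alternative — stay nearly convex.  Because the VOI
clips spicule tips at 19 mm, the relative deviation of the largest phantoms
sits just above the 0.1 threshold and individual large phantoms can fall
below it; the class contrast is asserted on medians.  A `rotation` argument produces the analytically rotated twin of a
phantom (rotating the radial function before rasterisation), the clean way to
probe descriptor rotation invariance without voxel-resampling artefacts.

What the phantoms do *not* emulate: attached vessels and pleural walls,
partial-volume and reconstruction-kernel effects, CT noise spectra, and the
label noise of reader panels.  Passing the synthetic benchmark therefore
demonstrates that each descriptor measures the contrast it was designed for
and that the two-stage classifier integrates them — not clinical-grade
performance on real CT.

## Known limitations

* The PSCSS aggregate is only approximately rotation invariant: with 5
  sections and ~50 lobe crossings per scale, the hypergeometric fluctuation
  of which spicules the sections cross leaves a 13–25% relative L1 spread
  between a phantom and its rotated twin.  The spread shrinks roughly as the
  inverse square root of the section count (≈11% at 16 views).
* The seven-voxel star clique is a documented stand-in for the much richer
  clique geometry of high-order MGRF texture models; it preserves the
  energy-image-plus-histogram contract, not any particular published
  potential set.
* Reversal counts and code histograms are computed on rasterised masks;
  sub-voxel contour refinement is out of scope.
* On the synthetic benchmark most descriptors saturate (≈97–100% accuracy),
  so the fusion stage's headroom over the best single descriptor cannot be
  demonstrated there; fusion's value shows in its robustness to single
  uninformative inputs, which is tested directly.

## Problem sizes

The default benchmark is 200 phantoms (100/100), split 140/60, with all six
descriptors at their default operating points (ALBP 5 views/3 levels/
average-N; HOG 5³ blocks/3³ cells/dodecahedron full; MGRF Q=32/1000 bins;
PSCSS gap 15/5 views; SPHARM order 70; 7 geometric features).  A full run
(generation, extraction, both training stages, evaluation) takes ≈9 minutes
on one CPU core.
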