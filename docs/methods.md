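# Methods

This note records the models behind each pipeline stage, the parameter
defaults and why they hold, the numerical choices that matter, and what
the synthetic phantom does and does not establish about real scans.

## Measurement model

A restoration increment is scanned twice — uncured and cured — at 16 μm
isotropic voxels, reconstructed as 16-bit attenuation volumes.  The cured
scan differs from the uncured one by (a) a rigid pose change of the whole
sample, (b) the polymerization shrinkage of the composite, and (c) an
independent noise draw.  The analysis removes (a) by rigid registration
on static tooth anatomy and then reads (b) off the tracer spheres: for a
sphere with pre-cure centroid `p` and post-cure centroid `q`, the
shrinkage vector is `d = T⁻¹(q) − p` where `T` is the recovered pose.
All coordinates are μm; z runs from the occlusal (light-source) face
toward the cavity floor, so positive `dz` is movement toward the floor
and negative `dz` toward the light.  The sphere-level vectors — not
per-sample means — are the observations throughout, including the
statistics; this is deliberate pseudo-replication: the per-sphere
distribution is the quantity of interest, and one-way ANOVA is robust to
the mild non-normality of these distributions.

## Synthetic phantom

The phantom renders the scene analytically: a dentin block (cylindrical
collar plus floor) at attenuation 700 with a smooth seeded texture
(Gaussian-filtered white noise, σ = 3 voxels, amplitude 60), a water
background at 100, a cylindrical cavity holding one or more composite
layers (flowable 1000, hybrid 1400), and tracer beads at 400 rendered
with sub-voxel anti-aliasing (per-voxel coverage fractions from 3³
sub-samples).  Bead diameters are drawn uniformly from 40–70 μm and
centres are placed by rejection sampling with ≥ 48 μm centre spacing
(2 wt% tracer loadings are dilute, and closer pairs would merge into one
connected component at segmentation smoothing scales).  The texture is
not decoration: a homogeneous block would leave rotation about the
cavity axis unobservable to registration, and real dentin is not
homogeneous either.

The post scan re-renders the same scene with each bead centre displaced
by the analytic deformation field, the composite membership evaluated at
inverse-deformed positions (so the free surface and wall gaps deform
consistently), the whole scene mapped through the rigid pose, and a fresh
noise draw added.  Tooth voxels are static.  The deformation fields —
uniform contraction toward a centre, constant axial drift, an axial
swirl, and sums of these — are convenient analytic stand-ins that
reproduce the phenomenology of shrinkage fields (downward free-surface
movement, swirls in top view, upward flow near the floor); they are not a
mechanical model of curing.

Default scene sizes: 160³ voxels (2.56 mm cube) with a 1.6 mm × 1.2 mm
cavity and 300 beads for standard studies; a 72³ quick preset (0.64 mm
cavity, 60 beads) for replicated studies; and a full-scale preset with
the 6 mm × 4 mm cavity on a 440×440×320 grid for runs where memory and
time are no concern.  Noise `σ = 120` gives contrast-to-noise 5 between
bead and composite (contrast 600), the stressed condition used in the
validation studies.

What passing phantom tests does *not* show: robustness to beam hardening,
ring artifacts, the heterogeneous filler texture of hybrid composites
(which defeats bead detection in practice and is why air bubbles serve as
tracers there), reconstruction misalignment, or tooth deformation from
dehydration.  The phantom's edges are also sharper than a scanner PSF
would deliver; registration is masked away from edges partly for that
reason (below).

## Rigid registration

Masked normalized cross-correlation over the six rigid parameters
(intrinsic z-y-x Euler angles in degrees; translation in voxels during
optimization), maximized by Powell's method within a three-level
coarse-to-fine schedule: Gaussian smoothing σ = 4, 2, 1.5 voxels with up
to 20k/40k/60k deterministically strided mask points.  Everything is
seedless and deterministic.

Two masking rules matter:

* The **composite region is excluded** (cavity cylinder dilated by 3
  voxels): shrinkage is the signal, and any composite voxel in the metric
  would bias the pose toward absorbing it.  With the dentin-only mask,
  adding or removing the deformation changes the objective by nothing
  measurable.
* The mask is additionally **eroded 3 voxels into the dentin** so that it
  samples smooth texture interior rather than water/dentin step edges.
  Linearly interpolated step edges are sharpest at lattice-aligned
  offsets, which otherwise biases the NCC optimum toward integer-voxel
  translations (we measured up to 0.6 voxel of z bias from this effect
  on unsmoothed volumes).  The finest smoothing level stops at σ = 1.5
  voxels for the same reason: the interpolation-phase ripple of the noise
  term scales down with smoothing and changes sign near this scale.

Recovered accuracy on noise-free phantoms with poses up to 5 voxels and
3°: ≤ 0.05 voxel and ≤ 0.05° (worst of 20 random poses); under
contrast-to-noise 5 a residual bias of ±0.03 voxel remains.  The pose is
applied to sphere *coordinates* (post centroids mapped through `T⁻¹`),
never by resampling the post volume before segmentation — interpolation
would blur 2–4-voxel beads.  `resample()` exists for visual overlays
only.

## Sphere segmentation

Detection operates on a contrast image: per-z-slice median of the masked
voxels (composite layers are stratified in z) minus the lightly smoothed
volume (σ = 0.7 voxels), clipped at zero.  Otsu's threshold inside the
mask, 26-connected components, and two filters: component volume within
4–120 voxels (spheres of 2–6 voxel diameter, bracketing 40–70 μm beads
with partial-volume slack) and compactness ≥ 0.06.  Compactness is
component volume over the volume of the sphere whose radius is half the
bounding-box diagonal; an ideal sphere scores 3^(−3/2) ≈ 0.19 under this
definition and real thresholded 3–5-voxel blobs score as low as ≈ 0.09,
so 0.06 keeps beads while rejecting plates and threads.  Centroids are
centres of mass weighted by contrast squared — squaring concentrates the
weight in the blob core where the contrast-to-noise ratio is highest and
measurably reduces centroid noise (2.2 vs 2.4 μm RMSE at CNR 5).
Sphere ids are assigned in lexicographic centroid order, making output
independent of labeling order.  Air-bubble tracers use the same detector
with a lower fixed-fraction threshold preset.

A uniform (tracer-free) volume yields an empty sphere set, not an error;
an empty mask is an error.

## Sphere matching

For each pre-scan sphere, a 15³-voxel block centred on its centroid is
searched over the post scan (at the posed location) by exhaustive
integer-offset NCC within a 10-voxel radius, on volumes smoothed with
σ = 0.7 voxels so the score reflects bead structure rather than
per-voxel noise.  Ties break to the smallest displacement, then
lexicographically.  Zero-variance blocks get a no-score sentinel.  The
NCC peak predicts the partner position; the nearest post centroid within
a 32 μm gate is the candidate, conflicts resolve greedily by ascending
residual, and the result is strictly one-to-one.  Scores below 0.3 route
the sphere to the unmatched pool.

Two consistency passes follow, both standard in particle tracking:

* a **normalized-median outlier test** (8 nearest matched neighbours,
  threshold 2, noise floor 2 μm): shrinkage fields are spatially smooth,
  so a displacement far from its neighbourhood median is a
  correspondence error — typically a block that locked onto a
  neighbouring, nearly identical bead or onto cavity-wall structure;
* **guided re-matching** of unmatched spheres using the median
  displacement of their matched neighbours as the predictor, which
  recovers the spheres the first pass lost to such lock-ons.

On the stressed 160³/CNR-5/posed study this yields ≥ 99% true pairings
with per-bead displacement RMSE ≈ 0.2 voxel (3 μm).

## Vectors, summaries, glyphs

Vector records carry both centroids (post mapped into pre space), the
displacement, its magnitude and the signed z component, labeled by
group/sample/increment.  Cumulative rows (liner, liner + increment 1, …)
are concatenations of the constituent scan-pair fields under one label.
Summaries report n, mean ± SD (sample SD, n−1) of magnitude and z; a
single-record cell reports NaN SD with a flag.

Mean magnitudes of noisy vector fields are biased upward — for
displacement `d` and isotropic per-component noise σ,
`E|d + e|² = |d|² + 3σ²`, the same noncentral-chi effect familiar from
MRI magnitude images.  `noise_corrected_magnitudes` therefore estimates
σ from the field itself (1.4826 × MAD of residuals against the local
8-neighbour median displacement, deflated by the median's own variance
share) and reports `sqrt(max(|d|² − 3σ̂², 0))`.  The validation studies
use this debiased mean; at CNR 5 it recovers the analytic group mean to
a few percent, limited by the ±0.03-voxel registration bias noted above
(seed-to-seed spread ≈ ±3%, occasionally ~8%).  Noise-free fields are
essentially unaffected (σ̂ ≈ 0).

Glyph files are VTK legacy-ASCII polydata written and parsed by this
package: points are pre-cure centroids, the `displacement` array holds
*unscaled* vectors, `magnitude` is a scalar array for colour mapping, and
the conventional ×10 visibility factor is stored as the `glyph_scale`
field-data value rather than baked into the geometry, keeping the file
quantitative.

## Statistics

* `shapiro_wilk` — scipy's Shapiro–Wilk; samples above 5000 are tested
  on a fixed-seed subsample of 5000 (the statistic degenerates for huge
  n, and vector fields here reach 10⁴–10⁵ records).
* `one_way_anova` — sums of squares computed directly;
  `F = MS_between / MS_within`, df `(k−1, N−k)`.  Zero within-group
  variance with unequal means reports infinite F, p = 0, and a
  degeneracy flag.
* `tamhane_t2` — for each pair, Welch's t with Welch–Satterthwaite df
  and two-sided p; familywise adjustment `p_adj = 1 − (1 − p)^m` with
  `m = k(k−1)/2` (the classical T2 form; Bonferroni behind a flag).
  Under an all-null unequal-variance simulation (k = 5, n = 30, 2000
  replicates) the familywise error is ≈ 0.03 at α = 0.05 — conservative,
  as designed.
* `letters_from_pairs` — insert-and-absorb compact letter display;
  groups share at least one letter iff their comparison is not
  significant, verified exhaustively in the tests.

## Pipeline and reproducibility

The study runner validates every referenced path before any computation,
processes scan pairs independently, writes per-pair vector CSVs and
glyphs, pools cumulative cells, runs the statistics on magnitude and z,
and records a manifest (tool version, config hash, seed, per-stage
sphere/match/unmatched counts, recovered transforms).  Unmatched-sphere
counts are surfaced prominently: silent tracer attrition is the main
failure mode of this analysis.  Re-running an identical config produces
byte-identical CSVs; all randomness in the phantom derives from one seed
via independent spawned streams (placement, texture, pre-noise,
post-noise), and per-stage seeds derive deterministically from the
study's master seed.

Validation study sizes were chosen to exercise the stated conditions at
desk scale: the end-to-end study uses the 160³ default phantom with 300
beads at CNR 5; pose recovery uses 20 random poses on 112³ phantoms;
discrimination uses 100 replicate pairs of 72³ phantoms with 60 beads
per group at contraction 0.005 vs 0.02.

## Known limitations

* The deformation fields are kinematic stand-ins, not cure mechanics; no
  claim is made about stress.
* Registration accuracy statements assume the dentin collar is several
  voxels thick after mask erosion; very small fields of view (the 72³
  quick preset) under-constrain the pose and are used with known or
  disabled poses only.
* The matching consistency tests assume a spatially smooth displacement
  field; a genuinely discontinuous field (e.g. across a debonded
  interface) could see correct matches rejected near the discontinuity.
* Hybrid-composite filler texture, beam hardening and reconstruction
  artifacts are outside the phantom's noise model.
* Group comparisons treat spheres as independent observations; tooth- or
  sample-level random effects are not modeled.
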