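# shrinkvec

Micro-CT shrinkage-vector analysis of dental composite polymerization.

When a light-cured resin composite polymerizes inside a cavity, the
material contracts and its interior mass moves.  Scanning the restoration
by micro-CT before and after curing, with radiolucent tracer particles
(40–70 μm glass beads, or the air bubbles naturally present in highly
viscous composites) dispersed in the resin, makes that movement
measurable: each tracer found in both scans contributes one **shrinkage
vector** — its 3D displacement in μm.  The field of all vectors shows how
much and in which direction a restoration shrank, and its signed axial
(z) component separates movement toward the cavity floor (positive) from
movement toward the curing light (negative).

`shrinkvec` implements the full measurement chain for paired 16-bit
volumes at 16 μm voxel size:

1. **Rigid registration** of the post-cure scan onto the pre-cure scan,
   driven only by static tooth anatomy (masked normalized
   cross-correlation, 3-level multi-resolution, deterministic Powell
   search), so sample repositioning between scans is removed while
   shrinkage is preserved.
2. **Sphere segmentation** of the radiolucent tracers inside the cavity:
   per-slice background estimation, Otsu thresholding, 26-connected
   components with size/shape filters, and contrast-weighted sub-voxel
   centroids (≈0.04 voxel RMSE on noise-free phantoms).
3. **Sphere matching** by exhaustive block-matching NCC for a coarse
   integer displacement, nearest-centroid gating for sub-voxel refinement,
   global one-to-one conflict resolution, and a normalized-median
   consistency test against the local displacement field.
4. **Shrinkage vectors**: per-sphere displacement records with magnitude
   `|d| = sqrt(dx² + dy² + dz²)` and signed z component, CSV tables, and
   VTK polydata glyph export (unscaled vectors plus the customary ×10
   visibility factor stored as metadata).
5. **Group statistics**: Shapiro–Wilk normality, one-way ANOVA
   `F = MS_between / MS_within`, Tamhane's T2 post hoc (pairwise Welch
   t with Welch–Satterthwaite df and Sidák-type familywise adjustment
   `p_adj = 1 − (1 − p)^m`), and a compact letter display in which groups
   sharing a letter do not differ significantly.

Because real scan pairs of this kind are not publicly available, the
package ships a first-class **synthetic phantom**: a dentin-like block
with seeded texture, a cylindrical cavity filled with composite layers,
anti-aliased tracer beads, an analytic shrinkage deformation (uniform
contraction, axial drift, swirl, or sums of these), a rigid inter-scan
pose, and Gaussian scanner noise — with every true trajectory recorded,
so the whole pipeline is validated by parameter recovery against ground
truth.

## Worked example

Simulate a phantom scan pair (72³ voxels, 1% uniform contraction toward
the cavity-floor centre, 40 beads, modest noise) and run the pipeline:

```sh
cat > phantom.yaml <<'YAML'
spec: {preset: small, seed: 12, noise_sd: 60.0, bead_count: 40}
deformation: {kind: uniform_contraction, center: floor, contraction_fraction: 0.01}
YAML
shrinkvec simulate --config phantom.yaml --out g0

cat > study.yaml <<'YAML'
seed: 3
output_dir: out
cavity: {center_x: 576.0, center_y: 576.0, top_z: 160.0, diameter: 640.0, depth: 640.0}
registration: {enabled: false}
groups:
  - name: g0
    samples:
      - name: s1
        increments:
          - {label: inc1, pre: g0/pre.mha, post: g0/post.mha}
YAML
shrinkvec run --config study.yaml
```

The run prints

```
INFO shrinkvec.pipeline: g0_s1_inc1: 40/40 pre spheres matched (0 post unmatched)
pipeline complete: 1 scan pairs
```

and `out/summary.csv` contains

```
group,increment,n,mean_magnitude,sd_magnitude,mean_z,sd_z,n1
g0,inc1,40,3.9594294942641932,1.8735219749044099,3.1983489118684267,2.1390125045308737,False
```

i.e. all 40 tracers were recovered, the mean shrinkage vector is 3.96 μm
(for this small cavity, 1% contraction over a mean tracer–centre distance
of ≈0.4 mm), and the mean axial component +3.20 μm is positive —
material moved toward the cavity floor, as a contraction centred on the
floor demands.  `out/glyphs_g0_s1_inc1.vtk` holds the same field as
polydata for 3D arrow rendering.

Multi-group, multi-increment studies list more groups in the config; the
pipeline then also writes per-measure ANOVA results, Tamhane T2 pairwise
tables and compact letters into the output directory and the manifest.

Library use mirrors the CLI: `generate_phantom`, `register_rigid`,
`segment_spheres`, `match_scan_pair`, `compute_vectors`,
`summarize_field`, `tamhane_t2` are all importable from `shrinkvec`, and
`shrinkvec.studies` bundles the ground-truth validation studies.

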