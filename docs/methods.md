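# Methods

This note documents the models, conventions and numerical choices behind
`ovamap`, and what the phantom-based validation does and does not show
about real scans.

## Coordinate and axis conventions

Volumes are 3D arrays with an isotropic voxel size in micrometres —
isotropy is a hard precondition, since all morphometry is done in 3D.
Array axes are given anatomical roles by an `AxisFrame`: the stack axis
runs dorsal→ventral, in-plane axis 1 anterior→posterior, in-plane axis 2
medial→lateral, with orientation flags naming the low-index end of each
axis. Table coordinates are in µm, origin at the volume corner, a voxel's
coordinate being its centre. The medial–lateral reading of the second
in-plane axis is a pure labelling convention for sector names.

## The phantom

### What it emulates

The phantom reproduces the image *statistics* the analysis depends on,
not the physics of tomography. The organ is a two-level ellipsoid
(default semi-axes 1250×1000×750 µm, matching an adult mouse ovary):
dimmer medulla core and a brighter cortex shell over the outer 25% of the
normalised radius. Default 8-bit intensities — stroma 110, cortex 130,
granulosa 190, CL tissue 160, oocyte 150, nucleus 90, zona ring 70,
antral fluid 60, vessels 50 — mirror the radiopacity ordering an iodine
stain produces (follicular tissue bright, fluid and vessels dark); the
exact values are arbitrary and configurable. Vessels are dark tubes along
polylines: by default one 150 µm trunk entering at the hilum and two
35 µm medulla branches.

Per-stage follicle structure (all geometry relative to follicle radius R):

- **T1–T3** (below the microCT detection limit): featureless tissue at
  reduced contrast; the pipeline is not expected to find them.
- **T4**: granulosa plus centred oocyte (0.5 R) *without* a zona ring;
  the whole patch is blended toward stroma with factor 0.6, emulating the
  reduced radiopacity of the smallest detectable follicles.
- **T5**: centred oocyte (0.45 R) with a dark zona ring and a darker
  nucleus (0.4 of the oocyte radius); no antrum.
- **T6**: 2–4 disjoint dark cavities (radius 0.17 R at radial position
  0.68 R, pairwise angular separation ≥ 60°) around a smaller oocyte.
- **T7**: one off-centre antrum with volume fraction drawn from
  U(0.10, 0.18); oocyte on the opposite side.
- **T8**: one large central antrum with fraction drawn from
  U(0.35, 0.45); the oocyte sits near the wall inside a granulosa cumulus
  that is anchored to the wall by a granulosa stalk crossing the antrum.
  A granulosa buffer (zona thickness + 2 voxels) is repainted around the
  oocyte so the dark zona ring can never merge with the dark antrum.
- **CL**: homogeneous mid-bright tissue; no oocyte, zona or antrum.

The zona ring thickness is `max(5 µm, 2 voxels)` so the ring stays closed
after digitisation at any supported resolution.

### Placement model

Follicle centres are uniform over the admissible region with hard
non-overlap (one-voxel default clearance), sampled by rejection with the
largest spheres placed first. Centres of stages up to T5 are restricted
to the cortex shell, reflecting where recruitment happens; antral stages
and CLs may sit anywhere. In scaled-down test organs the cortex shell can
be geometrically thinner than a follicle radius, so the cortex threshold
adapts to 90% of the outermost reachable normalised radius; full-scale
organs are unaffected. Requests whose total volume reaches 40% of the
organ volume are refused up front (rejection packing is infeasible well
below that), and an unplaceable follicle raises an error naming its
stage.

`sector_biased` mode multiplies the placement density in one chosen
sector by `bias_factor`, implemented by thinning against the maximal
weight; the thinning draw is consumed in homogeneous mode too, so
`bias_factor = 1` reproduces homogeneous placement bit-for-bit at equal
seed. Note that with hard non-overlap the *realised* enrichment saturates
below the nominal factor once the biased sector approaches its packing
limit (at 400 follicles of ~89 µm the nominal ×4 realises roughly ×2.3);
the power simulations measure the realised effect.

### Diameters

Stage diameters are Normal(mean, SD) truncated at ±2 SD, with the stage
means/SDs of the staging rubric; truncation keeps every generated
diameter inside its stage's support so ground-truth staging is exact.
Corpora lutea have no published size statistics; the phantom draws CL
diameters from U(280, 450) µm. This is an explicit assumption, not a
measured value, and both the rubric's CL rule and the homogeneity report
flag it. Default per-stage counts (T4 64, T5 96, T6 90, T7 58, T8 16,
CL 10; total 334) reproduce a realistic adult census — T5/T6 most
numerous, T8 scarcest, and a CL count in the normal range for a cycling
mouse — while staying inside the packing budget.

### What the phantom does not emulate

No point-spread function, beam hardening, ring or cone-beam artifacts,
reconstruction noise correlations, intensity texture inside tissues, or
partial-volume blur: edges are sharp and noise is i.i.d. Gaussian.
Follicles never touch (clearance is configurable down to zero but the
default keeps them separated). Consequently, passing phantom tests shows
the *algorithmic* correctness of segmentation, morphometry, staging and
statistics — not robustness to scanner physics, stain variability, or
densely packed real tissue.

## Segmentation

The organ mask is the hole-filled largest connected component above a
global Otsu threshold. Follicle candidates: Gaussian smoothing (σ = 1
voxel), Otsu threshold over organ voxels (overridable), removal of small
objects, hole filling (which closes each follicle over its dark antrum,
zona and oocyte), then a Euclidean distance transform whose h-maxima
(depth 2 voxels) seed a watershed that splits touching objects. The
watershed machinery runs per connected blob on cropped subvolumes, which
is equivalent to, and much cheaper than, transforming the whole volume.
Candidates are filtered to equivalent-sphere diameters in [30, 600] µm,
and elongated objects (max-Feret over cross-section ratio > 3) are routed
to a separate vessel set. Ties in seed labelling follow array scan order,
so results are deterministic.

## Morphometry

The follicle "major diameter" is defined in 3D as the maximum caliper
(Feret) distance over the region's voxel-centre convex hull: it
upper-bounds every sectional diameter of a convex body, is
orientation-free, and agrees with the sectional definition for spheres.
For large regions the point cloud is first reduced to per-column extremes
(every hull vertex of an integer point set is a column extreme, so the
reduction is lossless), then the hull vertices are enumerated and the
diameter taken over vertex pairs. A single voxel measures one voxel by
convention. Tube calibres use `cross_section` mode: twice the maximum of
the Euclidean distance transform (the maximal inscribed sphere), the
natural diameter of an elongated object. Calibration: a digitised sphere
of radius 107 voxels at 1.5 µm/voxel measures 321.0 µm; radius 133 at
0.2 µm/voxel measures 53.2 µm; a radius-50-voxel cylinder at 1.5 µm/voxel
measures 150.0 µm, each within one voxel.

## Feature extraction

Dark interior structures are voxels below
`g_med − max(4·σ_MAD, 0.35·g_med)`, where `g_med` is the median intensity
of the region's outer shell (the granulosa) and `σ_MAD` its MAD-based
robust SD; the relative-drop term keeps the threshold meaningful on
noise-free images where the MAD vanishes. Each dark connected component
of at least the minimum cavity volume (a 10 µm sphere) is classified by
shape: if hole-filling grows it by ≥ 1.5× and the enclosed voxels form a
mid-intensity blob (between the dark threshold and 95% of `g_med`), the
component is a closed zona ring around the oocyte — `zp_present` and
`oocyte_present` are set, and any dark spots inside the enclosed blob
(the nucleus) are excluded from the cavity count. Remaining components
are antral cavities; `antrum_fraction` is the largest cavity volume over
the region volume. `mean_radiopacity` is the region mean over the organ's
99th-percentile intensity. On phantom ground-truth regions with noise
SD ≤ 5 these features reproduce the generated morphology exactly.

## Staging

Morphology outranks diameter, because adjacent stage diameter ranges
overlap (a +2 SD T7 is larger than the T7/T8 midpoint). Decision order:

1. no oocyte, no zona, no antrum, diameter ≥ 250 µm → **CL**;
2. ≥ 2 cavities → **T6**;
3. one cavity → **T8** if its volume fraction ≥ 0.3, else **T7**; the
   T7/T8 diameter midpoint (269.95 µm) decides only when the fraction is
   unmeasured;
4. no antrum with zona → **T5**;
5. no antrum, no zona, diameter within the T4 support
   [mean − 2 SD, mean + 2 SD] = [27.8, 78.6] µm → **T4**;
6. otherwise **unclassified** — never silently dropped, and each label
   carries a rationale string naming the rule that fired.

Two deliberate choices here: the single-antrum split uses the antrum
fraction (not `fraction OR diameter`), and the T4 upper bound is the +2 SD
support rather than the T4/T5 midpoint (71.1 µm). Both follow from
morphology-first consistency: the zona flag already separates T4 from T5,
and either midpoint rule would misclassify the upper diameter tail of
ground-truth T4/T7 follicles whose morphology is unambiguous. With these
rules the confusion matrix on ground-truth features is exactly diagonal.
Midpoint boundaries between all adjacent class means remain available via
`class_boundaries` for diameter-only fallback and reporting. The CL rule
has no published criteria; the 250 µm minimum is configurable and every
report carries a note that CL counts inherit this assumption.

## Sector partition and assignment

"Equally distributed sectors" is read as equal-extent quadrants: the
organ bounding box is split at its midplanes — dorsal/ventral along the
stack axis, then each half into quadrants by the anterior–posterior and
medial–lateral midplanes (mask-centroid midplanes are available via
config). Quadrants I/IV are anterior, II/III posterior; I/II medial.
Voxels exactly on a midplane go to the lower-index side. A follicle
belongs to the sector holding strictly more than half its voxels;
otherwise the maximal-overlap sector wins (ties broken in label order)
and the assignment is flagged as non-majority.

## Statistics

"Student's t-test" is the pooled-variance form (Welch available via
flag); two-group axis comparisons use per-ovary half totals. The
eight-sector comparison is a one-way ANOVA with the ovary as the
observational unit (counts per sector summarise one organ; three ovaries
give n = 3 per sector), followed by all 28 Bonferroni-adjusted pairwise
t-tests. A stage-abundance ANOVA across stage types is included. p-values
come from the t and F distribution functions, not Monte Carlo. Degenerate
zero-variance comparisons resolve to p = 1 when means agree and are
reported as maximally significant with a note otherwise; stages absent
from every ovary are skipped with a notice.

Two simulation harnesses close the loop: `typeI_error_simulation` draws
i.i.d. Poisson sector counts and verifies the ANOVA rejects at its
nominal level (with the per-sector mean 334/8 ≈ 41.75, 3 ovaries and 2000
replicates the empirical rate falls inside the 99% binomial band around
0.05), and `bias_power_simulation` verifies that a ×4 placement bias in
one sector is detected by ANOVA + post-hoc in > 90% of experiments
(50 experiments of 5 ovaries × 400 follicles).

## Problem sizes used in the test suite

Phantom-backed tests run on scaled-down organs (semi-axes 350–450 µm at
2–2.5 µm voxels, grids of 1–7×10⁷ voxels, 10–20 follicles) — the geometry
and intensity model are identical to full scale, only the object counts
and grid sizes are reduced. Placement-statistics tests use geometric
populations only (no voxelisation): 200 seeds × 240 follicles for the
chi-square calibration and 50 × 5 × 400 for the power study. The whole
suite completes in a few minutes on one CPU.

## Known limitations

- Validation is phantom-only; no real scan accompanies the package, so
  threshold defaults (Otsu, the dark-structure drop, h-maxima depth) may
  need tuning on real data.
- The watershed replacement for manual outlining is validated only on
  synthetic geometry; real follicle/theca boundaries are fuzzier.
- T1–T3 are generated but not detected — by design, mirroring the
  detection limit of the imaging protocol.
- The CL size rule and the CL diameter distribution are assumptions.
- The cumulus stalk is rendered but not measured; T8 is distinguished
  from T7 by antrum fraction, not stalk geometry.
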