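# ovamap

3D morphometry of the adult mouse ovary from contrast-enhanced microCT:
follicle staging, virtual sector mapping, and spatial homogeneity
statistics — with a digital ovary phantom generator that provides exact
ground truth for every stage of the pipeline.

## The problem

In the mouse, folliculogenesis proceeds through eight canonical growth
stages (Pedersen–Peters types T1–T8) ending in ovulation and a corpus
luteum (CL). Iodine-stained microCT reconstructs the intact ovary with
cubic voxels and isotropic micrometre resolution, which makes true 3D
follicle counting and spatial mapping possible: follicles from the
secondary T4 stage (53.2 ± 12.7 µm in diameter) to the fully grown antral
T8 stage (321.0 ± 21.3 µm) and CLs are resolved, along with the main
vessels (~150 µm at the hilum, ~35 µm in the medulla). The scientific
question downstream of the imaging is whether follicle recruitment is
spatially homogeneous: are follicles of each stage equally represented
between the dorsal/ventral and anterior/posterior halves, and across
eight virtual sectors of the organ?

`ovamap` implements that quantitative pipeline as a reusable package:

- **`ovamap.phantom`** — digital ovary phantoms: an ellipsoidal organ with
  cortex/medulla contrast, non-overlapping quasi-spherical follicles of
  all stages with stage-dependent internal structure (granulosa, antral
  cavities, zona pellucida ring, oocyte and nucleus), dark vessels, and
  Gaussian noise; exact per-voxel ground truth.
- **`ovamap.volio`** — multi-page TIFF / image-sequence volume I/O, CSV
  follicle tables, anatomical axis frames.
- **`ovamap.segment`** — organ mask, seeded-watershed follicle
  segmentation, 3D max-Feret and inscribed-sphere diameters, antrum/zona
  feature extraction.
- **`ovamap.rubric`** — deterministic staging of candidates into
  T4–T8 / CL / unclassified from morphology and diameter.
- **`ovamap.spatial`** — the eight-sector partition (D-I…D-IV,
  V-I…V-IV) and the >50%-volume sector assignment rule.
- **`ovamap.stats`** — pooled Student's t-tests, one-way ANOVA with
  Bonferroni post-hoc, homogeneity reports, and type-I-error / power
  simulation harnesses.

## The staging rubric

Each candidate is staged by morphology first, with diameter as a support
bound (see `docs/methods.md` for the full decision order):

| stage | diameter (µm) | signature |
|-------|---------------|-----------|
| T4 | 53.2 ± 12.7 | no zona pellucida space, reduced radiopacity |
| T5 | 89.0 ± 11.2 | zona pellucida, no antrum |
| T6 | 137.0 ± 24.9 | several scattered small antral cavities |
| T7 | 218.9 ± 36.9 | single modest antrum cavity |
| T8 | 321.0 ± 21.3 | single large antrum (≥ 30% of follicle volume) |
| CL | ≥ 250 (assumed) | no oocyte, no zona, no antrum |

## Worked example

Run the end-to-end demo (phantom → segment → classify → map-sectors →
analyze) on a scaled-down phantom ovary:

```bash
ovamap pipeline run --demo --out-dir demo-out --seed 1
```

This generates a 288×256×216-voxel phantom (2.5 µm voxels, organ
semi-axes 350×310×260 µm) containing 20 follicles, segments and stages
them, and writes `staged.csv`, `mapped.csv`, `counts.csv`, `report.json`
and inspection projections. On this run the recovered stage census

```
{'T4': 6, 'T5': 8, 'T6': 4, 'T7': 1, 'T8': 1}
```

matches the generated ground truth (`truth.csv`) exactly: every follicle
is found, measured (diameters within two voxels of truth) and staged
correctly. With ≥ 2 ovaries, `report.json` additionally contains the
axis t-tests and the eight-sector ANOVA with Bonferroni post-hoc, e.g.
via `ovamap analyze --mapped ovary1/mapped.csv --mapped ovary2/mapped.csv
--out report.json`.

The same stages are available individually (`ovamap generate-phantom`,
`ovamap segment`, `ovamap classify`, `ovamap map-sectors`,
`ovamap analyze`) and as library functions.

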