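# radius3d

Landmark-based 3D assessment of distal radius fracture displacement and
reduction.

Given pre- and post-operative wrist landmarks (and optionally shaft-surface
point clouds), `radius3d` constructs an anatomical coordinate frame from the
long axis of the intact radius shaft, expresses three articular reference
points (radial styloid process, sigmoid notch volar edge, sigmoid notch
dorsal edge) in that frame, and derives:

- per-point and centroid displacement vectors with anatomical direction
  labels (e.g. `ulnar-palmar-distal`),
- the reference-triangle plane area,
- 3D volar tilt (3D-VT) and 3D radial inclination (3D-RI), plus their
  2D radiograph-plane analogues,
- the cohort statistics: two-way ICC rater reliability, Shapiro–Wilk
  normality screening, Friedman test with a Scheffé-type rank post hoc,
  Wilcoxon signed-rank area comparison, and Pearson 2D–3D correlations.

A synthetic-cohort generator with exact ground truth makes every pipeline
stage testable without patient data.

## Layout

| module | contents |
| --- | --- |
| `radius3d.frame` | anatomical frame construction: long-axis fitting (slab-centroid PCA or least-squares cylinder), frame build, articular origin, point-to-point ICP registration, frame transforms |
| `radius3d.indices` | reference triads, centroid/area/VT/RI, displacement vectors and direction labels, 2D angles |
| `radius3d.stats` | ICC(2,1)/ICC(3,1), Shapiro–Wilk, tie-corrected Friedman (asymptotic or exact enumeration), Scheffé-type post hoc, Wilcoxon signed-rank, Pearson r |
| `radius3d.synthetic` | cylinder shaft clouds, hinge-rotation fracture displacement model, reproducible cohorts with stored truth |
| `radius3d.io` / `radius3d.pipeline` / `radius3d.cli` | landmark CSV/JSON + ASCII STL/PLY I/O, per-patient measurement, cohort report (JSON + text), CLI |

## CLI

```sh
# generate a synthetic cohort (landmarks.csv, truth.csv, optional PLY shafts)
radius3d simulate --out-dir sim --n-patients 52 --seed 1 --shaft-points 600

# lint a landmark file (exit code 2 on dialect violations)
radius3d validate sim/landmarks.csv

# per-patient measurements only
radius3d measure sim/landmarks.csv --out-dir meas --shaft-dir sim/shafts

# full workflow: frames -> indices -> statistics -> report.{json,txt}
radius3d cohort sim/landmarks.csv --out-dir report --shaft-dir sim/shafts

# re-run the statistics on an existing measurements.csv
radius3d stats report/measurements.csv --out stats.json
```

Landmark files are CSV (or equivalent JSON) with columns
`patient_id,stage,label,x,y,z`; stage is `pre`/`post`, label one of
`styloid`, `sigmoid_volar`, `sigmoid_dorsal`, `sigmoid_base`, `origin`,
coordinates in lab-frame millimetres. When no shaft clouds are supplied the
landmarks are assumed to be pre-registered in a shared anatomical frame.

## Conventions

- y-axis: radius long axis, proximal positive; z-axis: projected sigmoid
  base → styloid line, radial positive; x = y × z (dorsal positive on right
  wrists). yz/xy/xz planes are the coronal/sagittal/axial planes.
- 3D-VT is the signed angle of the sagittal-projected volar→dorsal edge
  line against the perpendicular to the long axis (palmar tilt positive);
  3D-RI the coronal-projected styloid→sigmoid-volar line angle
  (styloid-distal positive).
- Left wrists are mirrored (z negated) at ingestion so cohorts pool sides.

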