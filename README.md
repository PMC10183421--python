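# fibsafe

Safe drilling corridors on the lateral distal fibula for syndesmotic
stabilization devices.

Unstable syndesmotic injuries are stabilized with a suture-button system
pulled through a drill tunnel that runs from the lateral fibular cortex
through the fibula and tibia to a medial landing zone.  Because the
distal fibula is narrow, an eccentric tunnel can thin the anterior or
posterior cortex and invite peri-implant fracture.  `fibsafe` answers the
planning question geometrically, on 2-D axial cross-sections: *from which
segment of the lateral fibular cortex can a drill of diameter d reach a
fixed medial anchor without perforating the anterior or posterior
cortex?*

It is written for biomechanics and orthopaedic-research groups working
with cross-sectional bone geometry: the library ingests per-subject
contour + landmark files (or generates statistically realistic synthetic
cohorts), classifies the cross-sectional shape, simulates the three
device orientations, registers subjects by Procrustes superimposition,
and aggregates cohort safe corridors.

## Model in brief

A cross-section is a closed fibular contour with cortical apexes
7 (anterior), 8 (posterior), 9 (lateral).  Exit points on the lateral
cortex are expressed as signed percent of the cortical edge arc length
from the lateral apex (anterior +, posterior −, apex 0).  A tunnel of
diameter *d* about an axis through the fixed medial anchor **A** is safe
iff the axis enters the bone through the medial 7–8 face, exits through
the lateral cortex, and the strip of width *d* contains neither apex.
For convex sections the extreme feasible axes are the inner tangents
from **A** to the circles of radius *d*/2 about the apexes,

&nbsp;&nbsp;&nbsp;&nbsp;φ± = atan2(P − A) ± asin(d / 2‖P − A‖),  P ∈ {apex 7, apex 8},

and the per-subject feasible interval is [s(φ_post), s(φ_ant)] in signed
percent.  The cohort safe corridor of an angulated orientation is the
intersection of the per-subject intervals: upper = minᵢ anterior
borderᵢ, lower = maxᵢ posterior borderᵢ.  The center-center orientation
is the fixed axis through the anchor midpoint (point 10) and the apex
midpoint (point 11); its cohort corridor is the range of the exits.
Cohort registration is a three-landmark similarity Procrustes fit
(closed form, no reflection) with an iterated-mean-shape reference.

See `docs/methods.md` for the full model, the synthetic-cohort
definition, and numerical details.

## Worked example

```bash
fibsafe analyze --out results/demo --seed 1
```

runs the full pipeline on the default synthetic cohort (96 subjects,
3.5 mm drill) and prints

```
anterior_angulated: [-86.2%, -56.0%]
posterior_angulated: [62.9%, 85.9%]
center_center: [-23.8%, 33.8%]
report: results/demo/report.json
```

Reading: every subject in this cohort can accept an anteriorly angulated
3.5 mm tunnel starting between 56 % and 86 % of the way down the
*posterior* lateral cortex (negative values), a posteriorly angulated
tunnel starting 63–86 % up the *anterior* cortex, and the center-center
axes exit between 24 % posterior and 34 % anterior of the lateral apex.
The signs mirror the anchor geometry: a drill aimed at the anteromedial
landing zone must cross the bone obliquely and start posterior of the
lateral apex, and vice versa.  `results/demo/` also contains per-subject
tables (`shape_reports.csv`, `tunnel_solutions.csv`, `registration.csv`),
the serialized cohort, a run log, and SVG figures (pre/post-registration
overlay, corridors drawn on a reference outline).

The same run from Python:

```python
from fibsafe import CohortParams, PipelineConfig, run_pipeline

cfg = PipelineConfig(cohort=CohortParams(n_subjects=96, seed=1), seed=1)
result = run_pipeline(cfg)
print(result.report["corridors"]["corridors"]["anterior_angulated"])
# {'orientation': 'anterior_angulated', 'lower_pct': -86.2195671172,
#  'upper_pct': -55.9888053794, 'mode': 'intersection', 'empty': False,
#  'n_subjects': 96, 'n_infeasible': 0}
```

To analyze your own data, write one contour JSON per subject plus a
landmark CSV (`subject_id, point_id, x, y` with ids 1, 4, 7, 8, 9 — an
ImageJ multi-point CSV is also accepted) and run
`fibsafe analyze --input-dir <dir> --out <dir>`.  Left-sided subjects
are mirrored into a canonical right-sided frame at ingest.

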