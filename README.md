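# densemorph

Dense template-based 3D phenotyping of mandible-like bone surfaces.

Classical (cephalometric) shape assessment reduces an anatomical surface to a
few dozen manually indicated landmarks — slow, observer-dependent, and blind
to most of the shape. Dense phenotyping replaces them with thousands of
*quasi-landmarks*: the vertices of a fixed-topology template mesh that is
non-rigidly registered onto every subject's surface, so that vertex *k* lands
on the same anatomical location in every subject. `densemorph` implements
that pipeline for mandible-like surfaces, plus the complete statistical
framework used to validate it against manual landmarking, and a synthetic
mandible generator with exact ground truth so every stage can be tested
end to end without patient data.

## What is inside

| module | contents |
| --- | --- |
| `densemorph.meshkit` | `SurfaceMesh` / `LandmarkConfiguration` / `BarycentricPoint`, OBJ/PLY/STL and landmark-CSV I/O, exact closest-point queries with barycentric output, centroid size |
| `densemorph.registration` | similarity fit from positioning landmarks, rigid ICP, non-rigid ICP (`nonrigid_register`), the full `map_mandible` chain, generalized Procrustes analysis, template averaging |
| `densemorph.landmark_transfer` | barycentric embedding of manual landmarks (ML), template-landmark training, corresponding automatic landmarks (CAL), leave-one-out protocol |
| `densemorph.morphostats` | RMS-to-centroid reliability tables, principal variation axes, ML–CAL accuracy tables, Bland–Altman, balanced ANOVA variance components, ICC/SEM/RC, multivariate ICC on interlandmark distances |
| `densemorph.synthetic_data` | mandible-like base shape with the 26 canonical + 5 positioning landmarks, deformed populations with known dense correspondence, an "operated" variant, observer-noise and initialization-jitter simulators |
| `densemorph.study_runner` | `run_study`: simulate → map → transfer → validate, with provenance and a manifest from which every reported number is recomputable |

A thin CLI (`densemorph simulate / map / transfer / run-study / validate`)
wraps the same functions.

## The statistics at the core

For a landmark configuration `x_1..x_n` with centroid `x̄`, **centroid size**
is `CS = sqrt(Σᵢ ‖xᵢ − x̄‖²)`. Repeated indications of one landmark are
summarized by the **RMS distance to their centroid**,
`RMS = sqrt(meanᵢ ‖xᵢ − c‖²)`.

Agreement between manual and automatic centroid sizes is assessed with a
linear mixed model on the balanced jaw × observer × method layout. The
balanced-design ANOVA estimates of the variance components σ²_jaw,
σ²_observer, σ²_error (the error term carries the method contribution) give

```
SEM = sqrt(σ²_error)          standard error of measurement (mm)
RC  = 2.77 × SEM              reproducibility coefficient (mm)
ICC = σ²_jaw / (σ²_jaw + σ²_error)
```

Shape agreement uses the trace-based multivariate ICC over all
`n(n−1)/2 = 325` interlandmark distances of a 26-landmark configuration.

## Worked example

```python
import numpy as np
from densemorph import (
    NonRigidParams, deform_population, make_base_shape, nonrigid_register,
)

template, lm26, lm5 = make_base_shape(resolution=4, seed=0)   # 2562 vertices
truth = deform_population(template, 1, amplitude=3.0, seed=5,
                          base_landmarks=lm26, base_init_landmarks=lm5)
member = truth.members[0]                                     # known truth

cmap = nonrigid_register(template, member, NonRigidParams())
gt_err = np.linalg.norm(cmap.mapped_vertices - member.vertices, axis=1).mean()
print(f"mean surface distance {cmap.mean_surface_distance:.4f} mm")
print(f"mean ground-truth correspondence error {gt_err:.3f} mm")
```

prints

```
mean surface distance 0.0089 mm
mean ground-truth correspondence error 0.310 mm
```

i.e. the deformed template lies on the target surface to ~0.01 mm, and each
of the 2562 quasi-landmarks sits on average 0.31 mm from its true anatomical
correspondent — about a tenth of the 3 mm deformation that separated the two
shapes.

A full study replica (two samples, repeated observers, repeated mapping
rounds, all report tables) runs with:

```bash
densemorph run-study --seed 7 --out results/study
densemorph validate --report results/study/report.json --manifest results/study/manifest.json
```

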