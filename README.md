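# choroquant

Volumetric quantification of the choroid from structural OCT volumes:
en face **choroidal thickness** maps, **choroidal vascularity index (CVI)**
maps, fovea-centered regional means, and cluster-robust longitudinal
statistics across treatment visits — plus a synthetic phantom and cohort
generator so every stage can be validated against known ground truth.

## Who this is for

Researchers studying choroidal remodeling in exudative macular disease
(e.g. neovascular AMD treated with anti-VEGF injections) who want
whole-macula choroidal metrics from wide-field (12 × 12 mm) OCT volumes
rather than single-B-scan subfoveal measurements, and who need
statistics that respect the clustering of fellow eyes within patients.

## The measurement chain

For each eye-visit volume `I(y, x, z)` (A-scan grid `(y, x)`, depth `z`):

1. **Quality gate** — scans with device signal strength `< 7` are excluded.
2. **Attenuation compensation** — deep structures are shadowed by the
   tissue above them; each voxel is rescaled by the remaining tail
   energy of its A-scan,

   `Ĩ(z) = I(z)ⁿ / (2 Σ_{z'≥z} I(z')ⁿ + ε)`,  n = 2 by default,

   which cancels focal shadows and sharpens the choroidal–scleral
   interface (CSI).
3. **Surface segmentation** — Bruch's membrane (BM) and the CSI are
   extracted per B-scan as minimum-cost paths through the signed axial
   derivative (dynamic programming, smoothness-constrained, sub-voxel
   refinement), then median-filtered across B-scans.
4. **Thickness map** — `T(y, x) = (CSI − BM) · Δz` in µm.
5. **Vessel binarization** — choroidal vessel lumina are hyporeflective:
   a slab voxel is vessel if its (dB-scale, despeckled) compensated
   intensity falls below a global Otsu threshold computed from all slab
   voxels of the eye-visit.
6. **CVI map** — per A-scan, vessel voxels / slab voxels over
   `z ∈ [BM, CSI)`, a ratio in [0, 1].
7. **Registration** — follow-up visits are rigidly aligned
   (phase correlation over a rotation search) to the day-of-exudation
   visit using retinal-vessel projections, so the same area is compared
   across visits.
8. **Regions** — means are taken over a fovea-centered 5-mm circle, an
   11-mm circle, and the 6-mm-wide rim between their outer boundaries,
   excluding the optic nerve head and any per-visit manual exclusion
   masks (the union of all visits' exclusions applies to every visit).
   Eyes with more than 10% of the 5-mm circle excluded are ineligible
   for CVI analysis.
9. **Statistics** — per-eye visit-to-visit changes are analysed with
   OLS point estimates and a cluster-robust sandwich covariance
   `V = c (X'X)⁻¹ [Σ_g X_g'e_g e_g'X_g] (X'X)⁻¹` clustered on patient
   (CR1 small-sample factor, t reference with G−1 df), because fellow
   eyes of one patient are not independent.

## Worked example

```python
import numpy as np
from choroquant import (
    PhantomParams, PipelineConfig, RigidTransform2D,
    generate_longitudinal_phantoms, run_quantify,
)

series = generate_longitudinal_phantoms(
    PhantomParams(seed=3),                       # 64x64x256 desk-scale scan
    deltas=[(0.0, 0.0), (12.7, 0.014), (-6.8, -0.003)],  # um / CVI offsets
    transforms=[RigidTransform2D(),
                RigidTransform2D(1.5, -2.0, 1.5),
                RigidTransform2D(-2.0, 1.0, -0.75)],
)
res = run_quantify(PipelineConfig(), {v.visit_label: v for v, _ in series})
piv = res.records.query("region == 'circle5'").pivot_table(
    index="metric", columns="visit", values="value")
th = piv.loc["thickness_um"]
print(f"thickening at exudation: {th['exudation'] - th['pretreatment']:+.2f} um")
print(f"thinning after therapy:  {th['post_treatment'] - th['exudation']:+.2f} um")
```

prints

```
thickening at exudation: +12.48 um
thinning after therapy:  -19.19 um
```

— the programmed +12.7 µm thickening at the onset of exudation and the
−19.5 µm thinning after therapy, recovered through the full image chain
(compensation → segmentation → maps → registration → 5-mm-circle mean)
to within the segmentation's ~1 µm regional accuracy.

The same objects drive the cohort-level analysis:

```python
from choroquant import CohortParams, generate_cohort, cohort_to_records, run_analyze
rec = cohort_to_records(generate_cohort(CohortParams(seed=4)))
tables, report = run_analyze(PipelineConfig(), rec)
print(report)   # six summary tables: visit means ± SD, changes, cluster-robust p
```

A CLI wraps the same functions: `choroquant simulate | quantify |
register | analyze | cohort` (see `choroquant --help`).

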