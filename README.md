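# subshape

Vertex-wise subcortical shape morphometry for multi-site case-control
studies, with a fully synthetic test bed.

## The problem

Case-control neuroimaging consortia compare the *shape* of deep gray-matter
structures (pallidum, hippocampus, amygdala, thalamus, caudate, putamen,
accumbens) between patients and controls across many scanning sites.  Each
subject contributes triangle meshes of the 14 structures in vertex
correspondence with a template, and two per-vertex measures:

* **thickness** — the radial distance from a surface vertex to the
  structure's medial curve (mm);
* **surface area** — the log-Jacobian ln(A_subj(v) / A_tmpl(v)) of
  barycentric vertex areas against the template (local dilation).

The statistics follow the consortium pattern: within each site, a
mass-univariate GLM per vertex with age, sex, and intracranial volume as
covariates; the covariate-adjusted group effect converted to Cohen's
d = t·√(1/n₁ + 1/n₀); per-site effects pooled vertex-wise by
DerSimonian–Laird random-effects meta-analysis

    tau² = max(0, (Q − (k−1)) / C),   pooled = Σ wᵢ* dᵢ / Σ wᵢ*,   wᵢ* = 1/(vᵢ + tau²)

with v = (n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀)); and multiple comparisons handled
by a **searchlight FDR** applied separately within each structure: at level
q/L per radius of a ladder {2, 4, 8, ∞} mm, a vertex is significant if some
neighborhood of it certifies the Benjamini–Hochberg count condition
locally (with the ladder {∞} the procedure *is* per-structure BH at q).

Because such patient data are shared only on request, `subshape` also
ships a synthetic-data module that mirrors the study design — 6 sites, 412
patients / 368 controls, clinical subgroups (101 lifetime depression, 83
lifetime anxiety, 176 medicated), site offsets, and localized effects
injected on the reported (Cohen's d, percent change) scale — so the whole
pipeline is testable end to end against known truth, including effect
sizes taken from published subgroup findings (e.g. right-pallidum surface
area d = 0.174 / +4.5% in the depression subgroup).

## Worked example

Inject a detectable surface-area expansion in the right pallidum of the
depression subgroup and run the subgroup-vs-controls contrast end to end:

```python
import numpy as np
from subshape import (
    make_template_atlas, simulate_cohort, StudyData, run_contrast, ContrastSpec,
)
from subshape.simulate import EffectSpec, simulate_shape_maps

atlas = make_template_atlas()                      # 14 structures, 3,360 vertices
cohort = simulate_cohort(seed=42)                  # 412 patients / 368 controls, 6 sites

effect = EffectSpec(
    structure="pallidum", hemisphere="R", measure="logj",
    cluster_center=113, cluster_radius=4.0, d=0.5, pct=12.0,
    group_query="dx == 1 and dep_lifetime == 1",
)
maps = simulate_shape_maps(atlas, cohort, (effect,), seed=43)

spec = ContrastSpec(
    name="OCDdep_vs_controls",
    group_a="dx == 1 and dep_lifetime == 1",
    group_b="dx == 0",
)
res = run_contrast(StudyData(atlas, cohort, maps), spec)
print(res.clusters.to_string(index=False))
```

prints

```
          contrast structure hemisphere measure  n_vertices   peak_d  mean_pct  min_radius
OCDdep_vs_controls  pallidum          R    logj          11 0.779448 13.432862         2.0
```

— a single significant cluster of 11 vertices, exactly in the injected
right-pallidum surface-area map, first certified at the 2-mm searchlight.
The pooled estimates over the injected cluster recover the truth:

```python
cols = effect.vertices(atlas)
ms = res.meta["logj"]
print(f"pooled d: {ms.d[cols].mean():.3f}")                       # 0.511  (injected 0.5)
print(f"percent change: {100*np.expm1(ms.beta[cols]).mean():.2f}%")  # 12.54%  (injected 12%)
```

Contrasts for clinical subgroups, patient-vs-patient comparisons, clinical
regressions within patients (`run_clinical_regression`), and age-by-group
moderator analyses (`run_moderator`) use the same machinery.  A `subshape`
CLI wraps the library (`simulate`, `extract`, `analyze`, `report`) for
config-driven runs producing `clusters.csv`, vertex-level `meta_*.csv`
tables, and PLY overlays with `pooled_d` / `neglog10p` / `significant`
per-vertex properties.

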