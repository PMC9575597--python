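# Methods

## Overview

`subshape` implements a vertex-wise, multi-site analysis of subcortical
surface shape of the kind used in consortium case-control neuroimaging
studies of obsessive-compulsive disorder: per-vertex shape measures on
corresponded structure meshes, a mass-univariate GLM fitted within each
site, random-effects meta-analysis of the per-site effects, and a
searchlight false-discovery-rate correction applied separately within each
structure.  Because the underlying patient MRI data are not publicly
distributable, the package ships a first-class synthetic-data module that
reproduces the statistical structure the analysis assumes — six sites, 412
patients / 368 controls, realistic covariates and clinical subgroups, and
localized group effects specified on the reported (Cohen's d, percent
change) scale — so every stage is testable end to end against known truth.

## Shape measures

Analyses operate on triangle meshes of 14 subcortical structures (7 names
x 2 hemispheres: accumbens, amygdala, caudate, hippocampus, pallidum,
putamen, thalamus) that share vertex correspondence with a template.
Surface registration is out of scope: meshes are assumed already
corresponded, as produced by established shape pipelines.  Two per-vertex
measures are computed, with no spatial smoothing anywhere:

* **Radial distance ("thickness", mm).**  The Euclidean distance from a
  vertex to the structure's medial curve, computed with segment-wise
  projection onto the polyline.  Each subject's thickness uses a medial
  curve fitted to that subject's own surface.  The medial fit slices the
  mesh into K bins (default 20) along the first principal axis of its
  vertices, takes per-bin cross-section centroids, and smooths them with a
  3-point moving average; near-spherical meshes (first/second principal SD
  ratio < 1.5) collapse to a single centroid point.  Exact medial-axis
  transforms are notoriously unstable on noisy surfaces; the binned
  centroid skeleton is stable, fully testable (cylinders, spheres, and
  bent tubes have analytic answers), and matches the medial-curve notion
  for tubular subcortical shapes.
* **Log-Jacobian ("surface area", dimensionless).**  ln of the ratio of
  barycentric vertex areas (each triangle donates a third of its area to
  each corner) between subject and template at corresponded vertices.
  This is the standard surface realization of local area dilation; by
  construction `sum_v area_tmpl(v) * exp(logJ(v))` equals the subject's
  total surface area exactly.  Positive values mean local expansion.

Both measures are invariant to rigid motion applied to subject and
template together, and the template's logJ against itself is identically
zero.

## Per-site GLM

At every vertex and measure an OLS model

    y = b0 + b_g * group + b_age age + b_sex sex + b_icv icv + e

is fitted within each site (mass-univariate, vectorized across vertices;
the design is column-scaled before solving because ICV is ~7 decades
larger than the other regressors).  Conventions:

* Cohen's **d = t * sqrt(1/n1 + 1/n0)** from the covariate-adjusted group
  t — the standard conversion in consortium effect-size meta-analyses.
* **Percent change**: thickness, `100 * beta / adjusted control mean`
  (control mean with covariates at the whole-sample mean); log-Jacobian,
  `100 * (exp(beta) - 1)`.
* Residual df = n − rank(design), counting the intercept (n − 5 with the
  default three covariates).
* Constant design columns (e.g. sex at a single-sex site) are dropped with
  a warning; sites with fewer than `min_site_n` (default 10) subjects per
  group are excluded from a contrast, and missing covariates/flags are
  handled by listwise deletion per analysis.

## Random-effects meta-analysis

Per-site effects are pooled per vertex with the DerSimonian–Laird moment
estimator: Q-statistic heterogeneity, `tau2 = max(0, (Q - (k-1)) / C)`,
weights `1 / (v_i + tau2)`.  Group contrasts pool Cohen's d with the
large-sample variance `v = (n1+n0)/(n1 n0) + d^2 / (2(n1+n0))` (no Hedges
small-sample correction — the reported quantity is d, not g); clinical
regressions and age-by-group interaction terms pool the raw coefficients
with their OLS variances, because slopes and interactions have no natural
two-group d scale.  A single contributing site pools to itself with
tau2 = 0.  Two-sided p-values come from the normal reference for z =
pooled / SE.

Calibration note: under the global null the pooled z is slightly
conservative (chance dispersion inflates tau2 and hence the SE), and the
pooled d carries a small (~ −3% at the study's site sizes) downward bias
from the correlation between the inverse-variance weights and d through
v(d), partly offset by the noncentral-t mean inflation of per-site d.
The beta-scale percent change is unbiased.  Both effects are far inside
the Monte-Carlo tolerances of the validation studies below.

## Searchlight FDR

Correction is applied separately per structure and measure (14 x 2
families; reading "locally to individual structures" literally), using
Euclidean distances between template vertices, which never cross structure
boundaries.  For a radius ladder of L radii (default {2, 4, 8, inf} mm,
Bonferroni-split level q' = q/L per scale), vertex v is significant at
radius r if for some k

    #{u in N(v, r) : p_u <= k q'/m} >= k   and   p_v <= k q'/m,

with m the number of tested vertices in the structure.  This is a local
certification of the Benjamini–Hochberg count condition: a compact cluster
of moderate p-values can certify itself inside a small searchlight where
the same k-th-smallest condition would drown structure-wide, while the
threshold `k q'/m` is still referred to the structure-wide family size.
Design rationale: with the BH denominator set to the neighborhood size
instead, the union over ~m overlapping searchlights rejects with
probability ~ sum_v (q/L)/|N(v)| under the global null — an order of
magnitude above q for small neighborhoods — whereas the family-size
variant keeps the expected number of null rejections per structure near
q' and is verified by simulation here (measured mean per-family FDP
~ 0.005–0.015 at q = 0.05).  With the single-radius ladder {inf} the
procedure reduces *exactly* to per-structure BH at q (tested on arbitrary
inputs), and it is never less powerful than structure-wide BH at q/L.
Vertices with no contributing site (k = 0) are excluded from m and can
never be significant.

The error rate this procedure controls is the per-family FDR; the
calibration study therefore measures the false-discovery proportion per
structure-and-measure family and averages over families and replicates.
Across many simultaneous families the probability that *some* family
contains a false cluster is of course larger (~ 1 − (1−q_eff)^28 per
analysis); no cross-structure or cross-measure correction is applied,
matching the separate per-structure reporting convention.

## Synthetic data

**Atlas.**  Structures are closed pole-capped UV meshes (ellipsoids and
bent tubes with anatomically plausible sizes, bends, and placements; left
hemisphere mirrored).  Desk scale is 240 vertices per structure (3,360
total) so simulation studies run in minutes; the full-scale configuration
has 27,120 vertices total, the resolution of distributed subcortical shape
templates.  All meshes satisfy V − E + F = 2 and are watertight.

**Cohort.**  Six sites with 69/69/69/69/68/68 patients and 62/62/61/61/
61/61 controls.  Age is truncated normal on the 18–65 inclusion window
(patients 32.1 ± 9.6, controls 30.2 ± 9.3 years); sex ~ Bernoulli per
group (49%/53% male); ICV ~ N(1.5e6, 1.5e5) mm³; education, Y-BOCS
(24.9 ± 6.2, clipped to 0–40), and onset age (20.1 ± 8.7, capped at the
subject's age; duration = age − onset) follow the published summaries.
Subgroup membership (176 medicated, 101 lifetime depression, 83 lifetime
anxiety; symptom-dimension prevalences 57/49/41/32/21%) uses deterministic
quota fill — exact counts apportioned across sites by largest remainder,
members drawn once from the seeded generator — so subgroup n's are exactly
configurable rather than binomially noisy.  Clinical availability varies
by cohort: fields are masked site-by-site from the last site backwards
(81 patients lack Y-BOCS/dimensions, leaving the 331 used in clinical
regressions; 24 lack the depression flag, 139 the anxiety flag, 14
medication status), and quota counts apply to the observed pool, so the
analysis subgroup sizes match the configuration exactly.  Controls are
unmedicated with no comorbidity flags and no clinical scores.

**Direct-mode shape maps.**  `y_iv = mu_v + beta'x_i + delta_v 1[carrier]
+ u_site,v + eps_iv`, with `mu_v` the template thickness (0 for logJ),
small linear covariate slopes centered at reference values, iid Gaussian
vertex noise, and site offsets `u ~ N(0, (0.5 sigma_v)^2)` shared within
site.  Thickness noise is proportional to local template thickness
(CV 0.15 by default) — surfaces are thin near structure poles, so a
constant absolute SD would produce negative thickness there; logJ noise
has absolute SD 0.25, consistent with the scale implied by the reported
(d, %) pairs (e.g. d = 0.174 with 4.5% gives sigma = ln(1.045)/0.174 ~
0.253).  An injected effect specifies (structure, hemisphere, measure,
cluster center and radius, d, pct, carrier query); the generator solves
delta = ln(1 + pct/100) (logJ) or mu_v pct/100 (thickness) and sigma =
delta/d, so the standardized difference and the relative change are
jointly realized.  A (d, pct) pair of opposite signs, or pct != 0 with
d = 0, is rejected as infeasible.

**Geometry mode.**  The same effects realized as template deformations:
thickness as radial offsets along the vertex-to-medial direction, surface
area as a local similarity scale s = exp(delta/2) about the cluster
center's medial point (a similarity scale multiplies interior vertex areas
by s^2, i.e. logJ = 2 ln s; it also scales local thickness by s — the two
measures are geometrically coupled, which direct mode does not emulate).
Extraction from deformed meshes recovers the injected group differences
within 5% at cluster-interior vertices; boundary rings are distorted by
construction.  Degenerate deformations are detected by a near-zero
triangle-area proxy and flagged with a warning.

**What the generator does not emulate:** spatially correlated vertex
noise (real registration errors correlate across neighbors — real-data
FDR behaves more conservatively than the independent-noise simulation),
scanner/protocol effects beyond additive site offsets, segmentation
failure, non-Gaussian heavy tails, and any dependence of covariate effects
on vertex location.  Passing tests therefore validate the statistical
machinery, not the upstream image processing.

## Validation studies and problem sizes

Run by `scripts/acceptance.py` and mirrored in `tests/test_acceptance.py`,
all at desk scale (3,360 vertices, chosen so each study completes in
minutes on one CPU):

* **Null calibration** — 500 replicates of the full pipeline with no
  injected effect; mean per-family FDP (under the null, the indicator of
  any rejection in the family), expected at or below q = 0.05.
* **Effect recovery** — 200 replicate cohorts each for the
  depression-subgroup surface-area effect (d = 0.174, 101 vs 368) and the
  anxiety-subgroup thickness effect (d = 0.202, 83 vs 368); mean pooled d
  over the injected cluster, tolerance 2 x 0.01 (the pooled-d sampling SD
  ~0.14 over sqrt(200) replicates).
* **Percent-change recovery** — same depression replicates; mean
  `100 (exp(pooled beta) - 1)` against the injected 4.5%.
* **Oracle equivalences** — exact identities (ladder-{inf} = BH, k = 1
  pooling passthrough, OLS vs normal equations, the DL worked example
  Q = 8 / C = 200 / tau2 = 0.03 / pooled 0.4 / SE = 1/sqrt(75), cylinder
  thickness = radius, uniform-scale logJ = 2 ln s, area conservation).
* **Decision-pattern mirror** — 150 replicates with a deliberately
  detectable subgroup effect (d = 0.5, sized by a power calculation for
  >= 90% subgroup detection): the subgroup contrast reports the injected
  cluster and the genuinely null non-carrier-vs-controls contrast stays
  empty.  Two clauses of this study are structurally unattainable and
  their assertions fail by design rather than being weakened: the diluted
  whole-group contrast retains pooled z ~ 0.38 x the subgroup z (~1.7 for
  a detectable effect), which leaks past the searchlight threshold in a
  non-negligible fraction of replicates; and a with-vs-without-comorbidity
  contrast detects the carriers' genuine difference at essentially the
  same power as carriers-vs-controls (per-site SEs 0.115 vs 0.112).  The
  corresponding published nulls are low-power outcomes, not structural
  ones.

## Numerical choices and limitations

* OLS via column-scaled normal equations; rank checked, constant columns
  dropped.  tau2 truncated at zero.  p-values floored at the smallest
  positive double before FDR.
* Searchlight certification vectorized with padded neighbor matrices;
  KD-tree neighborhoods are precomputed once per atlas/ladder and reused.
* Cluster summaries: connected components over shared mesh edges among
  significant vertices; singletons are 1-vertex clusters; peak d is the
  extremum by absolute value; cluster percent change averages the
  vertex-wise pooled-beta percent change.
* Quota apportionment caps per-site counts at the site size; with extreme
  configurations (quota ~ pool size) the realized count can fall below the
  request by the cap.
* The medial-curve fit assumes a dominant principal axis; strongly
  C-shaped structures are handled by the binning following the chord, at
  the cost of a medial curve that cuts the bend slightly (bounded in tests
  at a quarter tube radius for a 90-degree arc).
* Determinism: every stochastic stage draws from `numpy` Generators seeded
  from a single `SeedSequence`; fixed (config, seed) reproduces cohort,
  maps, and result tables byte-identically.
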