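"""Named simulation scenarios mirroring the study design.

Each scenario bundles the cohort configuration, the injected effects, and
the contrast that targets them.  The recovery scenarios inject the
subgroup effects at their reported magnitudes (right-pallidum surface-area
expansion of d = 0.174 / +4.5% in patients with lifetime depression;
right-pallidum thickening of d = 0.202 / +4.3% in patients with lifetime
anxiety), so estimator bias can be measured against known truth.  The
pattern-mirror scenario instead injects a deliberately detectable subgroup
effect (d = 0.5) to probe the qualitative decision pattern — subgroup
contrasts should flag their clusters while the diluted whole-group
contrast should not — at realistic site sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .driver import ContrastSpec
from .simulate import EffectSpec

__all__ = [
    "DEP_SURFACE_PALLIDUM",
    "ANX_THICKNESS_PALLIDUM",
    "POWER_MATCHED_DEP",
    "CONTRAST_DEP_VS_CONTROLS",
    "CONTRAST_ANX_VS_CONTROLS",
    "CONTRAST_MAIN",
    "CONTRAST_DEP_VS_NODEP",
]

# A mid-ring vertex of the desk-scale right pallidum, away from the poles.
PALLIDUM_CLUSTER_CENTER = 113
CLUSTER_RADIUS_MM = 4.0

DEP_SURFACE_PALLIDUM = EffectSpec(
    structure="pallidum",
    hemisphere="R",
    measure="logj",
    cluster_center=PALLIDUM_CLUSTER_CENTER,
    cluster_radius=CLUSTER_RADIUS_MM,
    d=0.174,
    pct=4.5,
    group_query="dx == 1 and dep_lifetime == 1",
)

ANX_THICKNESS_PALLIDUM = EffectSpec(
    structure="pallidum",
    hemisphere="R",
    measure="thickness",
    cluster_center=PALLIDUM_CLUSTER_CENTER,
    cluster_radius=CLUSTER_RADIUS_MM,
    d=0.202,
    pct=4.3,
    group_query="dx == 1 and anx_lifetime == 1",
)

# Power-matched mirror effect: same location and carrier subgroup as the
# depression surface-area effect, amplified so the subgroup contrast is
# well powered at the study's site sizes (pooled |z| ~ 4.5).
POWER_MATCHED_DEP = EffectSpec(
    structure="pallidum",
    hemisphere="R",
    measure="logj",
    cluster_center=PALLIDUM_CLUSTER_CENTER,
    cluster_radius=CLUSTER_RADIUS_MM,
    d=0.5,
    pct=12.0,
    group_query="dx == 1 and dep_lifetime == 1",
)

CONTRAST_MAIN = ContrastSpec(name="OCD_vs_controls")
CONTRAST_DEP_VS_CONTROLS = ContrastSpec(
    name="OCDdep_vs_controls",
    group_a="dx == 1 and dep_lifetime == 1",
    group_b="dx == 0",
)
CONTRAST_ANX_VS_CONTROLS = ContrastSpec(
    name="OCDanx_vs_controls",
    group_a="dx == 1 and anx_lifetime == 1",
    group_b="dx == 0",
)
CONTRAST_DEP_VS_NODEP = ContrastSpec(
    name="OCDdep_vs_OCDnodep",
    group_a="dx == 1 and dep_lifetime == 1",
    group_b="dx == 1 and dep_lifetime == 0",
)
CONTRAST_NODEP_VS_CONTROLS = ContrastSpec(
    name="OCDnodep_vs_controls",
    group_a="dx == 1 and dep_lifetime == 0",
    group_b="dx == 0",
)
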