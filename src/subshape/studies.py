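"""Calibration and recovery studies over replicate simulated cohorts.

These are the package's own validation experiments: a global-null
calibration of the searchlight FDR pipeline, effect-size recovery for the
injected subgroup effects, and the qualitative decision-pattern study
(subgroup contrasts detect their injected cluster; the diluted whole-group
contrast should not report it).

The false-discovery proportion is measured at the level of the correction
family — one structure and one measure, matching how the correction is
applied — and averaged over families and replicates.  Under a global null
every rejection is false, so the per-family FDP is the indicator of any
rejection in that family.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .atlas import TemplateAtlas, make_template_atlas
from .cohort import CohortConfig, simulate_cohort
from .driver import ContrastSpec, StudyData, run_contrast
from .fdr import DEFAULT_LADDER, build_neighborhoods
from .maps import MEASURES
from .simulate import EffectSpec, simulate_shape_maps

__all__ = ["null_fdp_study", "recovery_study", "pattern_study"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def null_fdp_study(
    n_replicates: int,
    seed: int,
    q: float = 0.05,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    atlas: TemplateAtlas | None = None,
) -> dict:
    """Global-null calibration of the full pipeline.

    Each replicate simulates the default six-site cohort (412/368) with no
    injected effect, runs the main case-control contrast end to end for
    both measures, and records the false-discovery proportion of every
    correction family (14 structures x 2 measures).  Returns the mean FDP
    and its Monte-Carlo standard error.
    """
    atlas = atlas or make_template_atlas()
    nb = build_neighborhoods(atlas, ladder)
    seeds = _child_seeds(seed, 2 * n_replicates)
    spec = ContrastSpec(name="OCD_vs_controls")
    fdp = []
    for i in range(n_replicates):
        cohort = simulate_cohort(seed=int(seeds[2 * i]))
        maps = simulate_shape_maps(atlas, cohort, (), seed=int(seeds[2 * i + 1]))
        res = run_contrast(StudyData(atlas, cohort, maps), spec, q=q, neighborhoods=nb)
        for m in MEASURES:
            for key in atlas.keys():
                sl = atlas.slices[key]
                fdp.append(float(res.sig[m].significant[sl].any()))
    fdp = np.asarray(fdp)
    return {
        "mean_fdp": float(fdp.mean()),
        "mc_se": float(fdp.std(ddof=1) / np.sqrt(len(fdp))),
        "n_replicates": n_replicates,
        "n_families": len(fdp),
    }


def recovery_study(
    effect: EffectSpec,
    contrast: ContrastSpec,
    n_replicates: int,
    seed: int,
    atlas: TemplateAtlas | None = None,
) -> dict:
    """Effect-size recovery at the injected cluster.

    Each replicate draws a fresh cohort and shape maps with ``effect``
    injected, runs the per-site GLM and random-effects pooling for the
    targeted measure, and records the pooled Cohen's d and the pooled-beta
    percent change averaged over the effect vertices.
    """
    atlas = atlas or make_template_atlas()
    nb = build_neighborhoods(atlas)
    spec = replace(contrast, measures=(effect.measure,))
    cols = effect.vertices(atlas)
    seeds = _child_seeds(seed, 2 * n_replicates)
    d_all = np.empty((n_replicates, len(cols)))
    pct_means = []
    for i in range(n_replicates):
        cohort = simulate_cohort(seed=int(seeds[2 * i]))
        maps = simulate_shape_maps(atlas, cohort, (effect,), seed=int(seeds[2 * i + 1]))
        res = run_contrast(StudyData(atlas, cohort, maps), spec, neighborhoods=nb)
        ms = res.meta[effect.measure]
        d_all[i] = ms.d[cols]
        if effect.measure == "logj":
            pct_means.append(100.0 * np.expm1(ms.beta[cols]).mean())
        else:
            pct_means.append(100.0 * (ms.beta[cols] / ms.control_mean[cols]).mean())
    d_means = d_all.mean(axis=1)
    pct_means = np.asarray(pct_means)
    return {
        "mean_d": float(d_means.mean()),
        # MC SE treating the replicate as the unit, at single-vertex
        # resolution (the pooled-d sampling SD over replicates)
        "d_mc_se": float(d_all.std(ddof=1, axis=0).mean() / np.sqrt(n_replicates)),
        "d_cluster_mc_se": float(d_means.std(ddof=1) / np.sqrt(n_replicates)),
        "mean_pct": float(pct_means.mean()),
        "pct_mc_se": float(pct_means.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "n_effect_vertices": int(len(cols)),
    }


def pattern_study(
    effect: EffectSpec,
    contrasts: tuple[ContrastSpec, ...],
    n_replicates: int,
    seed: int,
    q: float = 0.05,
    atlas: TemplateAtlas | None = None,
) -> dict:
    """Qualitative decision pattern with a subgroup-only injected effect.

    For each replicate, every contrast runs end to end; a contrast
    "reports" the effect if its cluster table contains a row for the
    injected structure, hemisphere, and measure.  Returns the report rate
    per contrast name.
    """
    atlas = atlas or make_template_atlas()
    nb = build_neighborhoods(atlas)
    seeds = _child_seeds(seed, 2 * n_replicates)
    rates = {spec.name: 0 for spec in contrasts}
    for i in range(n_replicates):
        cohort = simulate_cohort(seed=int(seeds[2 * i]))
        maps = simulate_shape_maps(atlas, cohort, (effect,), seed=int(seeds[2 * i + 1]))
        data = StudyData(atlas, cohort, maps)
        for spec in contrasts:
            res = run_contrast(data, replace(spec, measures=(effect.measure,)), q=q, neighborhoods=nb)
            hit = (
                (res.clusters.structure == effect.structure)
                & (res.clusters.hemisphere == effect.hemisphere)
                & (res.clusters.measure == effect.measure)
            ).any()
            rates[spec.name] += int(hit)
    return {name: count / n_replicates for name, count in rates.items()} | {
        "n_replicates": n_replicates
    }
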