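"""Study orchestration: contrasts, clinical regressions, moderator analyses.

Each analysis follows the same multi-site plan: fit the vertex-wise GLM
within every eligible site, pool the per-site effects with random-effects
meta-analysis, correct with searchlight FDR per structure, and summarize
the surviving vertices as connected clusters.  Group contrasts are defined
by a pair of pandas query strings over the cohort table (e.g. patients
with lifetime depression vs controls); sites contribute only if both
groups reach ``min_site_n`` after listwise deletion of missing covariates,
and excluded sites are recorded in the result's log.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .atlas import TemplateAtlas
from .fdr import DEFAULT_LADDER, Neighborhoods, SignificanceMap, build_neighborhoods, searchlight_fdr
from .glm import DEFAULT_COVARIATES, SiteStats, fit_site_glm, percent_change
from .maps import MEASURES, ShapeMaps
from .meta import MetaStats, meta_map, pool_effects

__all__ = [
    "ContrastSpec",
    "StudyData",
    "ContrastResult",
    "run_contrast",
    "run_clinical_regression",
    "run_moderator",
    "summarize_clusters",
]

CLUSTER_COLUMNS = [
    "contrast",
    "structure",
    "hemisphere",
    "measure",
    "n_vertices",
    "peak_d",
    "mean_pct",
    "min_radius",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison over the cohort.

    ``group_a``/``group_b`` are pandas query strings selecting disjoint
    subject sets (group_a is coded 1).  ``moderators`` optionally adds
    age-by-group interaction terms ("age_x_group", "age2_x_group") whose
    coefficients are pooled on the beta scale.
    """

    name: str
    group_a: str = "dx == 1"
    group_b: str = "dx == 0"
    measures: tuple[str, ...] = MEASURES
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    moderators: tuple[str, ...] = ()


@dataclass
class StudyData:
    atlas: TemplateAtlas
    cohort: pd.DataFrame
    maps: ShapeMaps


@dataclass
class ContrastResult:
    name: str
    meta: dict[str, MetaStats]
    sig: dict[str, SignificanceMap]
    clusters: pd.DataFrame
    sites_used: list[str]
    sites_excluded: dict[str, str]
    moderator_meta: dict[str, dict[str, MetaStats]] | None = None
    moderator_sig: dict[str, dict[str, SignificanceMap]] | None = None


def _select_site_rows(
    cohort: pd.DataFrame, spec: ContrastSpec
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cohort restricted to the two groups, with the 0/1 group code."""
    a = cohort.query(spec.group_a)
    b = cohort.query(spec.group_b)
    overlap = a.index.intersection(b.index)
    if len(overlap):
        raise ValueError(f"contrast {spec.name!r}: group selectors overlap ({len(overlap)} subjects)")
    sub = pd.concat([a, b])
    g = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    return sub, g


def _listwise(sub: pd.DataFrame, g: np.ndarray, columns) -> tuple[pd.DataFrame, np.ndarray]:
    keep = sub[list(columns)].notna().all(axis=1).to_numpy()
    return sub.iloc[keep.nonzero()[0]], g[keep]


def run_contrast(
    data: StudyData,
    spec: ContrastSpec,
    q: float = 0.05,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    min_site_n: int = 10,
    neighborhoods: Neighborhoods | None = None,
) -> ContrastResult:
    """Full pipeline for one group contrast: per-site GLM -> random-effects
    meta-analysis -> searchlight FDR -> cluster table."""
    cohort = data.cohort.reset_index(drop=True)
    sub_all, g_all = _select_site_rows(cohort, spec)
    sub_all, g_all = _listwise(sub_all, g_all, spec.covariates)
    if neighborhoods is None:
        neighborhoods = build_neighborhoods(data.atlas, ladder)

    moderator_cols = []
    if spec.moderators:
        sub_all = sub_all.copy()
        # age centered per site before forming the interactions
        cage = sub_all["age"] - sub_all.groupby("site")["age"].transform("mean")
        if "age_x_group" in spec.moderators:
            sub_all["age_x_group"] = cage * g_all
            sub_all["age2"] = cage**2
        if "age2_x_group" in spec.moderators:
            sub_all["age2"] = cage**2
            sub_all["age2_x_group"] = cage**2 * g_all
        moderator_cols = [m for m in spec.moderators]

    sites_used: list[str] = []
    sites_excluded: dict[str, str] = {}
    per_site: dict[str, list[SiteStats]] = {m: [] for m in spec.measures}
    for site in sorted(cohort["site"].unique()):
        mask = (sub_all["site"] == site).to_numpy()
        sub, g = sub_all.iloc[mask.nonzero()[0]], g_all[mask]
        n1, n0 = int((g == 1).sum()), int((g == 0).sum())
        if n1 < min_site_n or n0 < min_site_n:
            sites_excluded[site] = f"group sizes {n1}/{n0} below min_site_n={min_site_n}"
            continue
        rows = data.maps.rows_for(sub["subject_id"])
        covs = list(spec.covariates) + (["age2"] if moderator_cols else [])
        for m in spec.measures:
            per_site[m].append(
                fit_site_glm(
                    data.maps.measures[m][rows],
                    sub,
                    g,
                    measure=m,
                    covariates=tuple(covs),
                    moderators=tuple(moderator_cols),
                    site=site,
                )
            )
        sites_used.append(site)
    if not sites_used:
        raise ValueError(
            f"contrast {spec.name!r}: no eligible site for selectors "
            f"({spec.group_a!r} vs {spec.group_b!r})"
        )

    meta: dict[str, MetaStats] = {}
    sig: dict[str, SignificanceMap] = {}
    tables = []
    for m in spec.measures:
        meta[m] = meta_map(per_site[m], scale="d")
        sig[m] = searchlight_fdr(
            meta[m].p, data.atlas, q, neighborhoods, k_sites=meta[m].k
        )
        tables.append(summarize_clusters(sig[m], meta[m], data.atlas, spec.name, m))
    clusters = _concat_cluster_tables(tables)

    moderator_meta = moderator_sig = None
    if moderator_cols:
        moderator_meta, moderator_sig = {}, {}
        for term in moderator_cols:
            moderator_meta[term], moderator_sig[term] = {}, {}
            for m in spec.measures:
                eff = np.vstack([s.extra_beta[term][0] for s in per_site[m]])
                var = np.vstack([s.extra_beta[term][1] ** 2 for s in per_site[m]])
                pooled = pool_effects(eff, var)
                ms = MetaStats(
                    measure=m,
                    d=np.full_like(pooled["est"], np.nan),
                    d_se=np.full_like(pooled["est"], np.nan),
                    beta=pooled["est"],
                    beta_se=pooled["se"],
                    tau2=pooled["tau2"],
                    Q=pooled["Q"],
                    k=pooled["k"],
                    z=pooled["z"],
                    p=pooled["p"],
                )
                moderator_meta[term][m] = ms
                moderator_sig[term][m] = searchlight_fdr(
                    ms.p, data.atlas, q, neighborhoods, k_sites=ms.k
                )

    return ContrastResult(
        name=spec.name,
        meta=meta,
        sig=sig,
        clusters=clusters,
        sites_used=sites_used,
        sites_excluded=sites_excluded,
        moderator_meta=moderator_meta,
        moderator_sig=moderator_sig,
    )


def run_clinical_regression(
    data: StudyData,
    variable: str,
    q: float = 0.05,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    min_site_n: int = 10,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    measures: tuple[str, ...] = MEASURES,
    neighborhoods: Neighborhoods | None = None,
) -> ContrastResult:
    """Vertex-wise association of a clinical variable within patients.

    Per-site OLS slopes for ``variable`` (Y-BOCS total, duration, onset
    age, or a 0/1 symptom dimension) are pooled on the beta scale.  Sites
    where the variable is constant (or with fewer than ``min_site_n``
    complete patients) are excluded for that regression.
    """
    cohort = data.cohort.reset_index(drop=True)
    patients = cohort.query("dx == 1")
    needed = [variable, *covariates]
    patients = patients[patients[needed].notna().all(axis=1)]
    if neighborhoods is None:
        neighborhoods = build_neighborhoods(data.atlas, ladder)

    sites_used, sites_excluded = [], {}
    per_site: dict[str, list[SiteStats]] = {m: [] for m in measures}
    for site in sorted(cohort["site"].unique()):
        sub = patients[patients["site"] == site]
        if len(sub) < min_site_n:
            sites_excluded[site] = f"{len(sub)} complete patients below min_site_n={min_site_n}"
            continue
        if sub[variable].nunique() < 2:
            sites_excluded[site] = f"{variable} constant within site"
            continue
        rows = data.maps.rows_for(sub["subject_id"])
        for m in measures:
            per_site[m].append(
                fit_site_glm(
                    data.maps.measures[m][rows],
                    sub,
                    variable,
                    measure=m,
                    covariates=covariates,
                    site=site,
                )
            )
        sites_used.append(site)
    if not sites_used:
        raise ValueError(f"no eligible site for clinical regression on {variable!r}")

    meta, sig, tables = {}, {}, []
    for m in measures:
        meta[m] = meta_map(per_site[m], scale="beta")
        sig[m] = searchlight_fdr(meta[m].p, data.atlas, q, neighborhoods, k_sites=meta[m].k)
        tables.append(summarize_clusters(sig[m], meta[m], data.atlas, f"regress_{variable}", m))
    return ContrastResult(
        name=f"regress_{variable}",
        meta=meta,
        sig=sig,
        clusters=_concat_cluster_tables(tables),
        sites_used=sites_used,
        sites_excluded=sites_excluded,
    )


def run_moderator(
    data: StudyData,
    q: float = 0.05,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    min_site_n: int = 10,
    neighborhoods: Neighborhoods | None = None,
) -> ContrastResult:
    """Age-by-diagnosis moderator analysis of the main contrast.

    Age is centered per site; linear and quadratic age-by-group
    interaction coefficients are pooled on the beta scale and FDR
    corrected like any other map.
    """
    spec = ContrastSpec(
        name="main_age_moderators",
        moderators=("age_x_group", "age2_x_group"),
    )
    return run_contrast(data, spec, q=q, ladder=ladder, min_site_n=min_site_n, neighborhoods=neighborhoods)


def _concat_cluster_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    tables = [t for t in tables if len(t)]
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=CLUSTER_COLUMNS)
    return out.sort_values(
        ["measure", "structure", "hemisphere"], kind="stable"
    ).reset_index(drop=True)


def summarize_clusters(
    sig: SignificanceMap,
    meta: MetaStats,
    atlas: TemplateAtlas,
    contrast: str,
    measure: str,
) -> pd.DataFrame:
    """Connected significant vertices (mesh-edge adjacency) as table rows.

    One row per cluster: vertex count, peak pooled d (extremum by absolute
    value), mean percent change over the cluster's vertices, and the
    smallest searchlight radius at which any cluster vertex passed.
    Singleton vertices form 1-vertex clusters.
    """
    rows = []
    for mesh in atlas.structures:
        sl = atlas.slices[mesh.key]
        mask = sig.significant[sl]
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        pos = {v: i for i, v in enumerate(idx)}
        edges = mesh.edges()
        keep = mask[edges[:, 0]] & mask[edges[:, 1]]
        e = edges[keep]
        n = len(idx)
        if len(e):
            i = np.array([pos[v] for v in e[:, 0]])
            j = np.array([pos[v] for v in e[:, 1]])
            graph = coo_matrix((np.ones(len(e)), (i, j)), shape=(n, n))
        else:
            graph = coo_matrix((n, n))
        ncomp, labels = connected_components(graph, directed=False)
        d = meta.d[sl]
        beta = meta.beta[sl]
        cm = meta.control_mean[sl] if meta.control_mean is not None else None
        radius = sig.radius[sl]
        for comp in range(ncomp):
            members = idx[labels == comp]
            dvals = d[members]
            if np.all(np.isnan(dvals)):
                peak = np.nan
            else:
                peak = dvals[np.nanargmax(np.abs(dvals))]
            if measure == "logj":
                pct = percent_change(beta[members], "logj").mean()
            elif measure == "thickness" and cm is not None and np.all(cm[members] > 0):
                pct = percent_change(beta[members], "thickness", cm[members]).mean()
            else:
                pct = np.nan
            rows.append(
                {
                    "contrast": contrast,
                    "structure": mesh.name,
                    "hemisphere": mesh.hemisphere,
                    "measure": measure,
                    "n_vertices": len(members),
                    "peak_d": peak,
                    "mean_pct": pct,
                    "min_radius": np.nanmin(radius[members]),
                }
            )
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
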