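"""Shape-data simulation with known injected group effects.

Direct mode (`simulate_shape_maps`) draws the per-vertex measures from the
generative model the downstream statistics assume:

    y_iv = mu_v + beta' x_i + delta_v [i in effect group] + u_{site(i),v} + eps_iv

with iid Gaussian vertex noise eps ~ N(0, sigma_v^2) and site offsets
u ~ N(0, (site_sd_ratio * sigma_v)^2) shared by all subjects of a site.
An injected effect is specified on the reported scale — a Cohen's d and a
percent change of the measure — and the generator solves for the mean
shift delta_v and the noise scale sigma_v that realize both jointly:

* log-Jacobian:  delta = ln(1 + pct/100),          sigma = delta / d
* thickness:     delta_v = mu_v * pct/100,         sigma_v = delta_v / d

so the standardized within-site group difference converges to d and the
relative change of the measure to pct.

Geometry mode (`simulate_subject_meshes`) realizes the same effects as
template-mesh deformations: radial offsets along the vertex-to-medial
direction for thickness, and local similarity scaling about the medial
curve for surface area (scale s dilates interior vertex areas by s^2, i.e.
logJ = 2 ln s).  Extracting measures from the deformed meshes recovers the
injected changes up to discretization error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import InvalidConfigError, TemplateAtlas
from .maps import MEASURES, ShapeMaps
from .shape import triangle_areas

__all__ = [
    "EffectSpec",
    "NoiseConfig",
    "CovariateEffects",
    "InfeasibleEffectError",
    "simulate_shape_maps",
    "simulate_subject_meshes",
]


class InfeasibleEffectError(ValueError):
    """An (d, pct) pair that admits no positive noise scale."""


@dataclass(frozen=True)
class EffectSpec:
    """A localized group effect on one structure and measure.

    The effect occupies the vertices of ``structure``/``hemisphere`` within
    ``cluster_radius`` mm (Euclidean, template space) of ``cluster_center``
    (a vertex index local to the structure) and applies to the subjects
    selected by the pandas query ``group_query`` (e.g. ``"dx == 1 and
    dep_lifetime == 1"``).  ``d`` is the standardized within-site group
    difference and ``pct`` the percent change of the measure's natural
    scale; the two jointly fix the vertex noise scale.
    """

    structure: str
    hemisphere: str
    measure: str
    cluster_center: int
    cluster_radius: float
    d: float
    pct: float
    group_query: str = "dx == 1"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise InvalidConfigError(f"unknown measure {self.measure!r}")
        if self.pct != 0.0 and self.d == 0.0:
            raise InfeasibleEffectError("pct != 0 with d = 0 admits no finite noise scale")

    def vertices(self, atlas: TemplateAtlas) -> np.ndarray:
        """Global vertex indices of the effect cluster."""
        mesh = atlas.get(self.structure, self.hemisphere)
        center = mesh.vertices[self.cluster_center]
        local = np.flatnonzero(
            np.linalg.norm(mesh.vertices - center, axis=1) <= self.cluster_radius
        )
        return atlas.slices[mesh.key].start + local

    def solve(self, mu_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean shift delta_v and noise scale sigma_v at the effect vertices."""
        mu_v = np.asarray(mu_v, dtype=float)
        if self.measure == "logj":
            delta = np.full(mu_v.shape, np.log1p(self.pct / 100.0))
        else:
            delta = mu_v * self.pct / 100.0
        if self.pct == 0.0:
            return delta, np.full(mu_v.shape, np.nan)   # sigma untouched
        sigma = delta / self.d
        if np.any(sigma <= 0.0):
            raise InfeasibleEffectError(
                f"d={self.d} and pct={self.pct} imply a nonpositive noise scale"
            )
        return delta, sigma


@dataclass(frozen=True)
class NoiseConfig:
    """Vertex noise scales and the site-offset SD ratio.

    Thickness noise scales with the local template thickness
    (``thickness_cv`` is the SD as a fraction of the vertex's template
    radial distance — surfaces are thin near structure poles, so absolute
    noise there must shrink for thickness to stay positive); log-Jacobian
    noise is an absolute SD.  Site offsets have SD ``site_sd_ratio *
    sigma_v``, shared by all subjects of a site, which creates the
    between-site heterogeneity the random-effects pooling absorbs.
    """

    thickness_cv: float = 0.15
    sigma_logj: float = 0.25
    site_sd_ratio: float = 0.5


@dataclass(frozen=True)
class CovariateEffects:
    """Linear covariate slopes of each measure, centered at reference
    values so baseline levels stay near the template."""

    thickness: tuple[float, float, float] = (-0.004, 0.05, 2.0e-7)   # age, sex, icv
    logj: tuple[float, float, float] = (-0.0008, 0.01, 5.0e-8)
    reference: tuple[float, float, float] = (31.0, 0.5, 1.5e6)

    def predict(self, measure: str, cohort: pd.DataFrame) -> np.ndarray:
        betas = np.asarray(getattr(self, measure))
        x = cohort[["age", "sex", "icv"]].to_numpy(dtype=float) - np.asarray(self.reference)
        return x @ betas


def _group_rows(cohort: pd.DataFrame, query: str) -> np.ndarray:
    idx = cohort.reset_index(drop=True).query(query).index.to_numpy()
    return idx


def simulate_shape_maps(
    atlas: TemplateAtlas,
    cohort: pd.DataFrame,
    effects: tuple[EffectSpec, ...] = (),
    noise: NoiseConfig | None = None,
    covariates: CovariateEffects | None = None,
    seed: int = 0,
) -> ShapeMaps:
    """Draw direct-mode shape maps for every subject in the cohort."""
    noise = noise or NoiseConfig()
    covariates = covariates or CovariateEffects()
    rng = np.random.default_rng(seed)
    cohort = cohort.reset_index(drop=True)
    n = len(cohort)
    vtot = atlas.total_vertex_count

    mu = {
        "thickness": atlas.template_thickness(),
        "logj": np.zeros(vtot),
    }
    sigma = {
        "thickness": noise.thickness_cv * mu["thickness"],
        "logj": np.full(vtot, noise.sigma_logj),
    }
    shift = {m: np.zeros((n, vtot)) for m in MEASURES}
    for eff in effects:
        cols = eff.vertices(atlas)
        delta, sig = eff.solve(mu[eff.measure][cols])
        if np.all(np.isfinite(sig)):
            sigma[eff.measure][cols] = sig
        rows = _group_rows(cohort, eff.group_query)
        shift[eff.measure][np.ix_(rows, cols)] += delta

    site_codes = pd.Categorical(cohort["site"]).codes
    n_sites = site_codes.max() + 1
    out = {}
    for m in MEASURES:   # fixed draw order for determinism
        site_offsets = rng.normal(0.0, noise.site_sd_ratio * sigma[m], size=(n_sites, vtot))
        eps = rng.standard_normal((n, vtot)) * sigma[m]
        out[m] = (
            mu[m][None, :]
            + covariates.predict(m, cohort)[:, None]
            + shift[m]
            + site_offsets[site_codes]
            + eps
        )
    return ShapeMaps(list(cohort["subject_id"]), out, dict(atlas.slices))


def simulate_subject_meshes(
    atlas: TemplateAtlas,
    cohort: pd.DataFrame,
    effects: tuple[EffectSpec, ...] = (),
    seed: int = 0,
    radial_noise_sd: float = 0.0,
) -> tuple[dict[str, dict[tuple[str, str], np.ndarray]], list[str]]:
    """Geometry mode: per-subject deformed template meshes.

    Returns ``(meshes, flagged)`` where ``meshes[subject_id][(structure,
    hemisphere)]`` is a (V, 3) vertex array in template correspondence and
    ``flagged`` lists subjects whose deformation degenerated (near-zero
    triangle area, a cheap self-intersection proxy).  With no effects and
    ``radial_noise_sd = 0`` the output equals the template bitwise.
    """
    rng = np.random.default_rng(seed)
    cohort = cohort.reset_index(drop=True)

    # per-effect precomputation in template space
    plans = []
    for eff in effects:
        mesh = atlas.get(eff.structure, eff.hemisphere)
        sl = atlas.slices[mesh.key]
        cols_global = eff.vertices(atlas)
        local = cols_global - sl.start
        mu = atlas.template_thickness()[cols_global]
        delta, _ = eff.solve(mu)
        rows = set(cohort.loc[_group_rows(cohort, eff.group_query), "subject_id"])
        if eff.measure == "thickness":
            dist, proj = mesh.medial_curve.nearest(mesh.vertices[local])
            direction = (mesh.vertices[local] - proj) / np.maximum(dist, 1e-12)[:, None]
            plans.append(("radial", mesh.key, local, delta[:, None] * direction, rows))
        else:
            _, proj0 = mesh.medial_curve.nearest(mesh.vertices[eff.cluster_center][None, :])
            scale = np.exp(delta / 2.0)[:, None]
            plans.append(("scale", mesh.key, local, (proj0[0], scale), rows))

    meshes: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    flagged: list[str] = []
    min_area = {
        m.key: 0.01 * triangle_areas(m.vertices, m.faces).min() for m in atlas.structures
    }
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        subject = {}
        bad = False
        for m in atlas.structures:
            v = m.vertices.copy()
            for kind, key, local, payload, members in plans:
                if key != m.key or sid not in members:
                    continue
                if kind == "radial":
                    v[local] += payload
                else:
                    anchor, scale = payload
                    v[local] = anchor + scale * (v[local] - anchor)
            if radial_noise_sd > 0.0:
                dist, proj = m.medial_curve.nearest(v)
                direction = (v - proj) / np.maximum(dist, 1e-12)[:, None]
                v += rng.normal(0.0, radial_noise_sd, size=len(v))[:, None] * direction
            if triangle_areas(v, m.faces).min() < min_area[m.key]:
                bad = True
            subject[m.key] = v
        if bad:
            warnings.warn(f"deformation degenerated for subject {sid}", RuntimeWarning)
            flagged.append(sid)
        meshes[sid] = subject
    return meshes, flagged
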