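"""Template atlas: corresponded triangle meshes for subcortical structures.

The atlas holds 14 closed tubular/ellipsoidal meshes (7 structure names x 2
hemispheres) with precomputed medial curves, standing in for a population
surface template.  Vertex order defines the correspondence: subject meshes
share the template's vertex indexing, so per-vertex measures are directly
comparable across subjects.

Two built-in sizes are provided.  The desk-scale atlas (240 vertices per
structure, 3,360 in total) keeps simulation studies fast; the full-scale
atlas has 27,120 vertices in total, the resolution at which consortium
subcortical shape templates are distributed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .shape import MedialCurve, fit_medial_curve, radial_distance

__all__ = [
    "STRUCTURE_NAMES",
    "HEMISPHERES",
    "AtlasConfig",
    "StructureMesh",
    "TemplateAtlas",
    "make_template_atlas",
    "InvalidConfigError",
]

STRUCTURE_NAMES = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)
HEMISPHERES = ("L", "R")


class InvalidConfigError(ValueError):
    """Raised for configuration values outside their valid domain."""


# Approximate anatomical geometry per structure: axis length, cross-section
# radius (mm), bend of the medial axis (deg), vertical flattening of the
# cross-section, and a right-hemisphere placement offset.  Left-hemisphere
# meshes are mirror images (x -> -x).
_GEOMETRY = {
    "accumbens": dict(length=12.0, radius=5.0, bend_deg=0.0, flatten=0.9, center=(9.0, 10.0, -8.0)),
    "amygdala": dict(length=18.0, radius=7.0, bend_deg=0.0, flatten=0.85, center=(24.0, -4.0, -16.0)),
    "caudate": dict(length=35.0, radius=5.0, bend_deg=100.0, flatten=0.9, center=(14.0, 8.0, 10.0)),
    "hippocampus": dict(length=40.0, radius=6.0, bend_deg=80.0, flatten=0.8, center=(28.0, -20.0, -10.0)),
    "pallidum": dict(length=20.0, radius=6.0, bend_deg=20.0, flatten=0.9, center=(19.0, 0.0, 0.0)),
    "putamen": dict(length=28.0, radius=7.0, bend_deg=30.0, flatten=0.8, center=(24.0, 2.0, 2.0)),
    "thalamus": dict(length=30.0, radius=9.0, bend_deg=20.0, flatten=0.9, center=(11.0, -2.0, 8.0)),
}

# Per-structure vertex budgets.  The full-scale budgets sum to 27,120 across
# the 14 meshes; desk scale is 240 per structure (3,360 total).
_FULL_BUDGETS = {
    "accumbens": 1198,
    "amygdala": 1402,
    "caudate": 2102,
    "hippocampus": 2252,
    "pallidum": 1502,
    "putamen": 2402,
    "thalamus": 2702,
}
_DESK_BUDGET = 240


@dataclass(frozen=True)
class AtlasConfig:
    """Atlas generation parameters.

    ``scale`` selects the built-in vertex budgets ("desk" or "full");
    ``budgets`` overrides them per structure name.  ``medial_samples`` is the
    number of polyline samples for the precomputed medial curves.
    """

    scale: str = "desk"
    budgets: dict | None = None
    medial_samples: int = 20
    size_scale: float = 1.0

    def budget_for(self, name: str) -> int:
        if self.budgets and name in self.budgets:
            return int(self.budgets[name])
        if self.scale == "desk":
            return _DESK_BUDGET
        if self.scale == "full":
            return _FULL_BUDGETS[name]
        raise InvalidConfigError(f"unknown atlas scale {self.scale!r}")


@dataclass
class StructureMesh:
    name: str
    hemisphere: str
    vertices: np.ndarray          # (V, 3) float, mm
    faces: np.ndarray             # (F, 3) int, 0-based
    medial_curve: MedialCurve

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.hemisphere)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges, shape (E, 2)."""
        f = self.faces
        e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
        return np.unique(e, axis=0)


def _grid_dims(budget: int) -> tuple[int, int, int]:
    """Rows/cols of the closed UV grid nearest a vertex budget.

    The meshes are pole-capped grids with V = rows*cols + 2; the budget is
    snapped up to the closest achievable count with rows, cols >= 3.
    """
    if budget < 12:
        raise InvalidConfigError(f"vertex budget {budget} < 12")
    n = budget - 2
    while True:
        divisors = [d for d in range(3, n // 3 + 1) if n % d == 0]
        if divisors:
            target = np.sqrt(n / 2.0)
            cols = min(divisors, key=lambda d: abs(d - target))
            return n // cols, cols, n + 2
        n += 1


def _tube_mesh(
    budget: int,
    length: float,
    radius: float,
    bend_deg: float,
    flatten: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed ellipsoid/bent-tube mesh in a canonical frame.

    The generating axis runs along x (bent into a circular arc in the x-y
    plane when ``bend_deg`` > 0); cross-sections are ellipses with radii
    (radius, flatten*radius) shrinking ellipsoidally toward pole caps.
    """
    rows, cols, _ = _grid_dims(budget)
    theta = np.linspace(0.0, np.pi, rows + 2)[1:-1]            # ring latitudes
    t = np.cos(theta)                                          # axial coord in [-1, 1]
    s = 0.5 * length * t                                       # arc-length position
    rho = np.sqrt(np.maximum(1.0 - t**2, 0.0))                 # ellipsoidal taper
    phi = np.linspace(0.0, 2.0 * np.pi, cols, endpoint=False)

    if bend_deg > 0.0:
        half = np.deg2rad(bend_deg) / 2.0
        arc_r = (0.5 * length) / half
        psi = s / arc_r
        centers = np.stack([arc_r * np.sin(psi), arc_r * (1 - np.cos(psi)), np.zeros_like(psi)], axis=1)
        normal = np.stack([-np.sin(psi), np.cos(psi), np.zeros_like(psi)], axis=1)
        pole_psi = np.array([half, -half])
        poles = np.stack([arc_r * np.sin(pole_psi), arc_r * (1 - np.cos(pole_psi)), np.zeros(2)], axis=1)
    else:
        centers = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
        normal = np.tile(np.array([0.0, 1.0, 0.0]), (rows, 1))
        poles = np.array([[0.5 * length, 0.0, 0.0], [-0.5 * length, 0.0, 0.0]])
    binormal = np.array([0.0, 0.0, 1.0])

    rings = (
        centers[:, None, :]
        + (radius * rho)[:, None, None] * np.cos(phi)[None, :, None] * normal[:, None, :]
        + (flatten * radius * rho)[:, None, None] * np.sin(phi)[None, :, None] * binormal[None, None, :]
    )
    vertices = np.concatenate([poles[:1], rings.reshape(-1, 3), poles[1:]], axis=0)

    faces = []
    top, bottom = 0, rows * cols + 1

    def ring_idx(i: int, j: int) -> int:
        return 1 + i * cols + (j % cols)

    for j in range(cols):
        faces.append([top, ring_idx(0, j + 1), ring_idx(0, j)])
    for i in range(rows - 1):
        for j in range(cols):
            a, b = ring_idx(i, j), ring_idx(i, j + 1)
            c, d = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(cols):
        faces.append([bottom, ring_idx(rows - 1, j), ring_idx(rows - 1, j + 1)])
    return vertices, np.asarray(faces, dtype=np.int64)


@dataclass
class TemplateAtlas:
    structures: list[StructureMesh]

    def __post_init__(self) -> None:
        self._index = {m.key: m for m in self.structures}
        offsets = np.cumsum([0] + [m.vertex_count for m in self.structures])
        self.slices = {
            m.key: slice(int(offsets[i]), int(offsets[i + 1]))
            for i, m in enumerate(self.structures)
        }

    def get(self, name: str, hemisphere: str) -> StructureMesh:
        return self._index[(name, hemisphere)]

    def keys(self) -> list[tuple[str, str]]:
        return [m.key for m in self.structures]

    @property
    def total_vertex_count(self) -> int:
        return sum(m.vertex_count for m in self.structures)

    def all_vertices(self) -> np.ndarray:
        """Template coordinates of every vertex, concatenated (V_total, 3)."""
        return np.concatenate([m.vertices for m in self.structures], axis=0)

    def template_thickness(self) -> np.ndarray:
        """Radial distance of the template surface itself (V_total,)."""
        return np.concatenate(
            [radial_distance(m.vertices, m.medial_curve) for m in self.structures]
        )

    def global_index(self, name: str, hemisphere: str, vertex: int) -> int:
        return self.slices[(name, hemisphere)].start + int(vertex)

    # ---- persistence (ASCII PLY per structure + medial curves) -----------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = []
        for m in self.structures:
            stem = f"{m.name}_{m.hemisphere}"
            ply = m.to_trimesh().export(file_type="ply", encoding="ascii")
            (directory / f"{stem}.ply").write_bytes(ply)
            np.savetxt(
                directory / f"{stem}_medial.csv",
                m.medial_curve.points,
                delimiter=",",
                header="x,y,z",
                comments="",
            )
            meta.append({"name": m.name, "hemisphere": m.hemisphere})
        (directory / "atlas.json").write_text(json.dumps({"structures": meta}, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TemplateAtlas":
        import trimesh

        directory = Path(directory)
        meta = json.loads((directory / "atlas.json").read_text())
        structures = []
        for entry in meta["structures"]:
            stem = f"{entry['name']}_{entry['hemisphere']}"
            mesh = trimesh.load(directory / f"{stem}.ply", process=False)
            medial = np.loadtxt(directory / f"{stem}_medial.csv", delimiter=",", skiprows=1)
            structures.append(
                StructureMesh(
                    name=entry["name"],
                    hemisphere=entry["hemisphere"],
                    vertices=np.asarray(mesh.vertices, dtype=float),
                    faces=np.asarray(mesh.faces, dtype=np.int64),
                    medial_curve=MedialCurve(medial),
                )
            )
        return cls(structures)


def make_template_atlas(config: AtlasConfig | None = None) -> TemplateAtlas:
    """Deterministically build the template atlas for a configuration."""
    config = config or AtlasConfig()
    structures = []
    for name in STRUCTURE_NAMES:
        geom = _GEOMETRY[name]
        verts, faces = _tube_mesh(
            config.budget_for(name),
            geom["length"] * config.size_scale,
            geom["radius"] * config.size_scale,
            geom["bend_deg"],
            geom["flatten"],
        )
        for hemi in HEMISPHERES:
            v = verts.copy()
            v += np.asarray(geom["center"])
            if hemi == "L":
                v[:, 0] *= -1.0
            medial = fit_medial_curve(v, faces, config.medial_samples, validate=False)
            structures.append(
                StructureMesh(
                    name=name,
                    hemisphere=hemi,
                    vertices=v,
                    faces=faces.copy(),
                    medial_curve=medial,
                )
            )
    return TemplateAtlas(structures)
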