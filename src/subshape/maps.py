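"""Per-subject vertex-wise shape measures, and extraction from meshes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import TemplateAtlas
from .shape import fit_medial_curve, log_jacobian, radial_distance

__all__ = ["ShapeMaps", "MEASURES", "extract_shape_maps"]

MEASURES = ("thickness", "logj")


@dataclass
class ShapeMaps:
    """Subjects x vertices matrices of the two shape measures.

    ``measures[m]`` has shape (n_subjects, V_total) with vertices
    concatenated across structures in atlas order; ``structure_slices``
    maps (name, hemisphere) to the column range of that structure.
    """

    subject_ids: list[str]
    measures: dict[str, np.ndarray]
    structure_slices: dict[tuple[str, str], slice]

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name, arr in self.measures.items():
            if arr.shape[0] != n:
                raise ValueError(f"measure {name!r} has {arr.shape[0]} rows for {n} subjects")
        self._row = {s: i for i, s in enumerate(self.subject_ids)}

    @property
    def n_vertices(self) -> int:
        return next(iter(self.measures.values())).shape[1]

    def rows_for(self, subject_ids) -> np.ndarray:
        return np.asarray([self._row[s] for s in subject_ids])

    def structure(self, measure: str, name: str, hemisphere: str) -> np.ndarray:
        return self.measures[measure][:, self.structure_slices[(name, hemisphere)]]

    # ---- long-form CSV interchange ---------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        records = []
        for (name, hemi), sl in self.structure_slices.items():
            v = np.arange(sl.stop - sl.start)
            for i, sid in enumerate(self.subject_ids):
                records.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "structure": name,
                            "hemisphere": hemi,
                            "vertex": v,
                            "thickness": self.measures["thickness"][i, sl],
                            "logj": self.measures["logj"][i, sl],
                        }
                    )
                )
        return pd.concat(records, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, atlas: TemplateAtlas) -> "ShapeMaps":
        subject_ids = list(dict.fromkeys(df["subject_id"]))
        n = len(subject_ids)
        vtot = atlas.total_vertex_count
        measures = {m: np.full((n, vtot), np.nan) for m in MEASURES}
        row = {s: i for i, s in enumerate(subject_ids)}
        for (name, hemi), sl in atlas.slices.items():
            sub = df[(df["structure"] == name) & (df["hemisphere"] == hemi)]
            r = sub["subject_id"].map(row).to_numpy()
            c = sl.start + sub["vertex"].to_numpy()
            for m in MEASURES:
                measures[m][r, c] = sub[m].to_numpy()
        return cls(subject_ids, measures, dict(atlas.slices))

    @classmethod
    def from_csv(cls, path, atlas: TemplateAtlas) -> "ShapeMaps":
        return cls.from_long_frame(pd.read_csv(path), atlas)


def extract_shape_maps(
    atlas: TemplateAtlas,
    subject_meshes: dict[str, dict[tuple[str, str], np.ndarray]],
    medial_samples: int = 20,
) -> ShapeMaps:
    """Compute both measures from corresponded subject meshes.

    ``subject_meshes`` maps subject id -> {(structure, hemisphere): (V, 3)
    vertex array in template vertex order}.  Thickness uses a medial curve
    fitted to each subject's own surface; the log-Jacobian compares
    barycentric vertex areas against the template.
    """
    subject_ids = list(subject_meshes)
    vtot = atlas.total_vertex_count
    thickness = np.empty((len(subject_ids), vtot))
    logj = np.empty((len(subject_ids), vtot))
    for i, sid in enumerate(subject_ids):
        for mesh in atlas.structures:
            sl = atlas.slices[mesh.key]
            verts = np.asarray(subject_meshes[sid][mesh.key], dtype=float)
            medial = fit_medial_curve(verts, mesh.faces, medial_samples, validate=False)
            thickness[i, sl] = radial_distance(verts, medial)
            logj[i, sl] = log_jacobian(verts, mesh.vertices, mesh.faces)
    return ShapeMaps(subject_ids, {"thickness": thickness, "logj": logj}, dict(atlas.slices))
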