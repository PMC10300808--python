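"""Readers and writers for the mesh and landmark formats the pipeline touches.

Meshes travel as PLY (ascii or binary little-endian) or binary STL, parsed
and serialised through trimesh.  STL carries no landmark or name data, so
landmark annotations always travel in a sidecar CSV/JSON in the landmark
dialect below; coordinates are assumed millimetres throughout.

Landmark dialects:
  * long CSV — columns specimen_id, sex, age, landmark_no (1-18), name,
    x_mm, y_mm, z_mm, one row per landmark (plus optional extra columns
    such as true_cluster for synthetic cohorts);
  * wide JSON — a list of objects {specimen_id, sex, age_years,
    landmarks: {code: [x, y, z]}}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .landmarks import LANDMARK_NAMES, LandmarkSet, validate_landmark_set
from .tps import TriangleMesh

__all__ = [
    "MeshFileRecord",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_landmarks_json",
    "write_landmarks_json",
]

_FORMATS = ("ply_ascii", "ply_binary_le", "stl_binary")


@dataclass(frozen=True)
class MeshFileRecord:
    path: Path
    format: str
    vertex_count: int
    face_count: int


def read_mesh(path: "str | Path", weld_tolerance: float = 1e-6) -> TriangleMesh:
    """Read a PLY or STL file into a TriangleMesh.

    STL stores independent facets, so its vertices are welded at
    ``weld_tolerance`` (mm) to recover shared topology; PLY vertices are
    taken as stored.  Quads, if present, are split fan-wise by the loader.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load(str(path), file_type=path.suffix.lstrip(".").lower(), process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path}: not a triangle mesh")
    if path.suffix.lower() == ".stl" and len(mesh.vertices):
        mesh.merge_vertices(digits_vertex=int(round(-np.log10(weld_tolerance))))
    return TriangleMesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
    )


def write_mesh(mesh: TriangleMesh, path: "str | Path", format: str = "ply_ascii") -> MeshFileRecord:
    """Write a TriangleMesh; output is bit-stable for fixed input and format."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write a mesh with no faces")
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if format == "ply_ascii":
        data = tm.export(file_type="ply", encoding="ascii")
    elif format == "ply_binary_le":
        data = tm.export(file_type="ply", encoding="binary")
    else:
        data = tm.export(file_type="stl")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return MeshFileRecord(
        path=path, format=format, vertex_count=len(mesh.vertices), face_count=len(mesh.faces)
    )


# ---------------------------------------------------------------------------
# landmark tables

_CSV_COLUMNS = ["specimen_id", "sex", "age", "landmark_no", "name", "x_mm", "y_mm", "z_mm"]


def write_landmarks(
    sets: Sequence[LandmarkSet],
    path: "str | Path",
    extra: "dict[str, Sequence] | None" = None,
    coordinate_frame: str = "raw_mm",
) -> None:
    """Write LandmarkSets to the long-CSV dialect.

    ``extra`` maps a column name to one value per specimen (e.g. the
    ground-truth cluster of a synthetic cohort).  ``coordinate_frame`` is
    recorded in a column so superimposed ("gpa_unit") and raw millimetre
    exports stay distinguishable.
    """
    rows = []
    for si, lm in enumerate(sets):
        for i, name in enumerate(LANDMARK_NAMES):
            row = {
                "specimen_id": lm.specimen_id,
                "sex": lm.sex,
                "age": "" if lm.age_years is None else lm.age_years,
                "landmark_no": i + 1,
                "name": name,
                "x_mm": repr(float(lm.points[i, 0])),
                "y_mm": repr(float(lm.points[i, 1])),
                "z_mm": repr(float(lm.points[i, 2])),
                "coordinate_frame": coordinate_frame,
            }
            if extra:
                for col, values in extra.items():
                    row[col] = values[si]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: "str | Path") -> list[LandmarkSet]:
    """Read the long-CSV dialect back into validated LandmarkSets."""
    df = pd.read_csv(path, dtype={"specimen_id": str}, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {', '.join(missing)}")
    sets = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        record = [(row["name"], (row.x_mm, row.y_mm, row.z_mm)) for _, row in sub.iterrows()]
        sex = str(sub["sex"].iloc[0]) if pd.notna(sub["sex"].iloc[0]) else "unknown"
        age = sub["age"].iloc[0]
        age_years = None if pd.isna(age) or age == "" else float(age)
        sets.append(
            validate_landmark_set(record, specimen_id=str(sid), sex=sex, age_years=age_years)
        )
    return sets


def read_landmark_table(path: "str | Path") -> pd.DataFrame:
    """The raw long-CSV table, for access to extra columns (true_cluster...)."""
    return pd.read_csv(path, dtype={"specimen_id": str})


def write_landmarks_json(sets: Sequence[LandmarkSet], path: "str | Path") -> None:
    """Write LandmarkSets to the wide-JSON dialect."""
    objs = []
    for lm in sets:
        objs.append(
            {
                "specimen_id": lm.specimen_id,
                "sex": lm.sex,
                "age_years": lm.age_years,
                "landmarks": {
                    name: [float(v) for v in lm.points[i]]
                    for i, name in enumerate(LANDMARK_NAMES)
                },
            }
        )
    Path(path).write_text(json.dumps(objs, indent=1))


def read_landmarks_json(path: "str | Path") -> list[LandmarkSet]:
    """Read the wide-JSON dialect back into validated LandmarkSets."""
    objs = json.loads(Path(path).read_text())
    return [
        validate_landmark_set(
            obj["landmarks"],
            specimen_id=str(obj.get("specimen_id", "")),
            sex=obj.get("sex", "unknown"),
            age_years=obj.get("age_years"),
        )
        for obj in objs
    ]
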