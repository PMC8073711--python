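"""File I/O: landmark tables, mesh/point-cloud files and report writing.

Landmark files are CSV (or an equivalent JSON list of records) with columns

    patient_id, stage, label, x, y, z

where stage is "pre"/"post", label one of styloid, sigmoid_volar,
sigmoid_dorsal, sigmoid_base, origin, and coordinates are lab-frame mm.
Shaft geometry is read from ASCII STL or PLY files; only vertices are used.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkFileError",
    "LANDMARK_LABELS",
    "REQUIRED_PRE_LABELS",
    "REQUIRED_POST_LABELS",
    "read_landmarks",
    "write_landmarks",
    "landmarks_to_frame",
    "load_mesh_vertices",
    "write_ply_points",
    "write_report",
]

LANDMARK_LABELS = ("styloid", "sigmoid_volar", "sigmoid_dorsal", "sigmoid_base", "origin")
REQUIRED_PRE_LABELS = ("styloid", "sigmoid_volar", "sigmoid_dorsal")
REQUIRED_POST_LABELS = LANDMARK_LABELS
STAGES = ("pre", "post")


class LandmarkFileError(ValueError):
    """A landmark file violates the documented dialect."""


def _records_from_csv(path: Path) -> list[dict]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"patient_id", "stage", "label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise LandmarkFileError(f"{path}: missing columns {sorted(missing)}")
    records = df.to_dict("records")
    for i, rec in enumerate(records):
        rec["_line"] = i + 2  # header is line 1
    return records

def _records_from_json(path: Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise LandmarkFileError(f"{path}: JSON landmark file must be a list of records")
    for i, rec in enumerate(data):
        rec["_line"] = i + 1
    return data


def read_landmarks(path) -> dict:
    """Parse a landmark file into ``{patient_id: {stage: {label: (3,) array}}}``.

    Malformed rows are reported with their line number; duplicate
    patient/stage/label rows and missing required labels raise
    :class:`LandmarkFileError`.
    """
    path = Path(path)
    records = _records_from_json(path) if path.suffix.lower() == ".json" else _records_from_csv(path)

    out: dict = {}
    errors: list[str] = []
    for rec in records:
        line = rec.get("_line", "?")
        pid = str(rec.get("patient_id", "")).strip()
        stage = str(rec.get("stage", "")).strip()
        label = str(rec.get("label", "")).strip()
        if not pid:
            errors.append(f"line {line}: empty patient_id")
            continue
        if stage not in STAGES:
            errors.append(f"line {line}: patient {pid}: unknown stage {stage!r}")
            continue
        if label not in LANDMARK_LABELS:
            errors.append(f"line {line}: patient {pid}, stage {stage}: unknown label {label!r}")
            continue
        try:
            xyz = np.array([float(rec["x"]), float(rec["y"]), float(rec["z"])])
        except (KeyError, TypeError, ValueError):
            errors.append(f"line {line}: patient {pid}, stage {stage}, label {label}: non-numeric coordinates")
            continue
        if not np.all(np.isfinite(xyz)):
            errors.append(f"line {line}: patient {pid}, stage {stage}, label {label}: non-finite coordinates")
            continue
        stage_map = out.setdefault(pid, {}).setdefault(stage, {})
        if label in stage_map:
            errors.append(f"line {line}: patient {pid}, stage {stage}: duplicate label {label!r}")
            continue
        stage_map[label] = xyz

    for pid, stages in out.items():
        for stage, required in (("pre", REQUIRED_PRE_LABELS), ("post", REQUIRED_POST_LABELS)):
            if stage not in stages:
                errors.append(f"patient {pid}: stage {stage!r} missing entirely")
                continue
            for label in required:
                if label not in stages[stage]:
                    errors.append(f"patient {pid}, stage {stage}: required label {label!r} missing")
    if errors:
        raise LandmarkFileError(f"{path}: " + "; ".join(errors))
    return out


def landmarks_to_frame(landmarks: Mapping) -> pd.DataFrame:
    """Flatten the nested landmark mapping into the CSV dialect DataFrame."""
    rows = []
    for pid in sorted(landmarks):
        for stage in STAGES:
            for label, xyz in landmarks.get(pid, {}).get(stage, {}).items():
                rows.append(
                    {
                        "patient_id": pid,
                        "stage": stage,
                        "label": label,
                        "x": float(xyz[0]),
                        "y": float(xyz[1]),
                        "z": float(xyz[2]),
                    }
                )
    return pd.DataFrame(rows, columns=["patient_id", "stage", "label", "x", "y", "z"])


def write_landmarks(landmarks: Mapping, path) -> None:
    """Write landmarks in the canonical CSV (or JSON) dialect."""
    path = Path(path)
    df = landmarks_to_frame(landmarks)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict("records"), indent=1) + "\n")
    else:
        df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# mesh / point-cloud files


def load_mesh_vertices(path) -> np.ndarray:
    """Read the vertices of an ASCII STL or PLY file as an (n, 3) array."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        return _read_ascii_stl(path)
    if suffix == ".ply":
        return _read_ascii_ply(path)
    raise ValueError(f"unsupported mesh format {suffix!r} (expected .stl or .ply)")


def _read_ascii_stl(path: Path) -> np.ndarray:
    verts = []
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head != b"solid":
        raise ValueError(f"{path}: binary STL is not supported; export ASCII STL")
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(v) for v in parts[1:4]])
    if not verts:
        raise ValueError(f"{path}: no vertices found")
    return np.unique(np.asarray(verts, dtype=float), axis=0)


def _read_ascii_ply(path: Path) -> np.ndarray:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertices = None
        props: list[str] = []
        in_vertex_element = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unexpected end of PLY header")
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "format" and parts[1] != "ascii":
                raise ValueError(f"{path}: only ASCII PLY is supported")
            if parts[0] == "element":
                in_vertex_element = parts[1] == "vertex"
                if in_vertex_element:
                    n_vertices = int(parts[2])
            elif parts[0] == "property" and in_vertex_element:
                props.append(parts[-1])
            elif parts[0] == "end_header":
                break
        if n_vertices is None:
            raise ValueError(f"{path}: PLY file has no vertex element")
        try:
            ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
        except ValueError as exc:
            raise ValueError(f"{path}: vertex element lacks x/y/z properties") from exc
        verts = np.empty((n_vertices, 3))
        for i in range(n_vertices):
            vals = fh.readline().split()
            verts[i] = [float(vals[ix]), float(vals[iy]), float(vals[iz])]
    return verts


def write_ply_points(points, path, comment: str = "") -> None:
    """Write a point cloud as a faceless ASCII PLY file."""
    pts = np.asarray(points, dtype=float)
    path = Path(path)
    lines = ["ply", "format ascii 1.0"]
    if comment:
        lines.append(f"comment {comment}")
    lines += [
        f"element vertex {len(pts)}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pts]
    path.write_text("\n".join(lines) + "\n")


def write_report(report: dict, path) -> None:
    """Serialise a cohort report dict to JSON with stable key order."""
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, allow_nan=True) + "\n")
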