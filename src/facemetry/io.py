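"""On-disk formats: PLY/OBJ meshes (via trimesh), landmark JSON,
region-label JSON.

Landmark files are a flat JSON object ``{"Prn": [x, y, z], ...}`` in
millimetres — diff-friendly and trivially hand-editable.  Region maps
are a JSON array of per-vertex label strings.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import trimesh

from .core import FaceMesh, LandmarkSet
from .errors import InvalidArgumentError, ParseError, UnsupportedFormatError

_MESH_EXTS = {".ply", ".obj"}


def _check_mesh_ext(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext not in _MESH_EXTS:
        raise UnsupportedFormatError(
            f"unsupported mesh format {ext!r} for {path!r}; use .ply or .obj"
        )
    return ext


def read_mesh(path: str) -> FaceMesh:
    """Read a triangulated mesh from a .ply or .obj file."""
    _check_mesh_ext(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(path, process=False, force="mesh")
        vertices = np.asarray(tm.vertices, float)
        faces = np.asarray(tm.faces, np.int64)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise ParseError(f"could not parse mesh file {path!r}: {exc}") from exc
    if vertices.size == 0:
        raise ParseError(f"mesh file {path!r} contains no vertices")
    return FaceMesh(vertices, faces)


def write_mesh(
    mesh: FaceMesh,
    path: str,
    vertex_colors: Optional[np.ndarray] = None,
    binary: bool = False,
) -> None:
    """Write a mesh to .ply (ASCII by default, binary little-endian on
    request) or .obj.  ``vertex_colors`` is an (n, 3) uint8 RGB array and
    is only supported for PLY."""
    ext = _check_mesh_ext(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if vertex_colors is not None:
        vertex_colors = np.asarray(vertex_colors)
        if vertex_colors.shape[0] != mesh.n_vertices:
            raise InvalidArgumentError("vertex_colors length must equal vertex count")
        if ext != ".ply":
            raise UnsupportedFormatError("vertex colors require the PLY format")
        tm.visual.vertex_colors = vertex_colors.astype(np.uint8)
    if ext == ".ply":
        tm.export(path, encoding="binary" if binary else "ascii")
    else:
        tm.export(path)


def read_vertex_colors(path: str) -> np.ndarray:
    """Read per-vertex RGB colors from a PLY file."""
    ext = os.path.splitext(path)[1].lower()
    if ext != ".ply":
        raise UnsupportedFormatError("vertex colors are stored in PLY files only")
    tm = trimesh.load(path, process=False, force="mesh")
    return np.asarray(tm.visual.vertex_colors)[:, :3].copy()


def read_landmarks(path: str) -> LandmarkSet:
    """Read a landmark set from a flat-JSON file (name -> [x, y, z] mm)."""
    ext = os.path.splitext(path)[1].lower()
    if ext != ".json":
        raise UnsupportedFormatError(f"unsupported landmark format {ext!r}; use .json")
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON in {path!r} at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"landmark file {path!r} must contain a JSON object")
    for name, p in data.items():
        if not (isinstance(p, (list, tuple)) and len(p) == 3):
            raise ParseError(f"landmark {name!r} in {path!r} is not a 3-element list")
    return LandmarkSet(data)


def write_landmarks(landmarks: LandmarkSet, path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext != ".json":
        raise UnsupportedFormatError(f"unsupported landmark format {ext!r}; use .json")
    with open(path, "w") as fh:
        json.dump(landmarks.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_region_labels(path: str) -> np.ndarray:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON in {path!r} at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(data, list):
        raise ParseError(f"region file {path!r} must contain a JSON array")
    return np.asarray(data, dtype=object)


def write_region_labels(labels: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        json.dump([str(x) for x in labels], fh)
        fh.write("\n")
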