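"""Core containers: triangulated face meshes, named landmark sets,
per-vertex region maps and rigid transforms.

Units are millimetres throughout; coordinates are right-handed with
X = subject's left, Y = superior, Z = anterior when a surface is in
its anatomical pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError, MissingLandmarkError

#: the nine facial region labels plus background
REGION_LABELS = (
    "forehead",
    "nose",
    "upper_lip",
    "lower_lip",
    "chin",
    "paranasal_L",
    "paranasal_R",
    "cheek_L",
    "cheek_R",
)
BACKGROUND = "background"

#: landmark names required for the full 19-measurement report
REQUIRED_LANDMARKS = (
    "Prn", "Ls", "Li", "LCh", "RCh", "Pg'", "Gn'", "Me'",
    "Sn", "Stos", "Stoi", "Sl", "CphL", "CphR", "Gl", "N'",
    "ExL", "ExR", "EnL", "EnR", "TraL", "TraR", "OrbL", "OrbR", "PhiF",
)

#: the eight landmarks whose 3D deviation is decomposed along the frame axes
DEVIATION_LANDMARKS = ("Prn", "Ls", "Li", "LCh", "RCh", "Pg'", "Gn'", "Me'")


@dataclass
class FaceMesh:
    """Triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex index triples
    region_labels : optional length-n array of region label strings
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidArgumentError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidArgumentError("faces must be an (m, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidArgumentError("vertex coordinates must be finite")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise InvalidArgumentError("face index exceeds vertex count")
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=object)
            if len(self.region_labels) != len(self.vertices):
                raise InvalidArgumentError(
                    "region_labels length must equal vertex count"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "FaceMesh":
        labels = None if self.region_labels is None else self.region_labels.copy()
        return FaceMesh(self.vertices.copy(), self.faces.copy(), labels)

    def transformed(self, transform: "RigidTransform") -> "FaceMesh":
        out = self.copy()
        out.vertices = transform.apply(out.vertices)
        return out

    def triangle_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (unit length)."""
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        normals = np.zeros_like(self.vertices)
        for i in range(3):
            np.add.at(normals, self.faces[:, i], fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return normals / norm


class LandmarkSet(Mapping[str, np.ndarray]):
    """Named anatomical points (mm). Behaves as a read-only mapping
    from landmark name to a 3-vector."""

    def __init__(self, points: Mapping[str, Iterable[float]]):
        self._points: Dict[str, np.ndarray] = {}
        for name, p in points.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise InvalidArgumentError(f"landmark {name!r} has non-finite coordinates")
            self._points[str(name)] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __iter__(self):
        return iter(self._points)

    def __len__(self):
        return len(self._points)

    def require(self, names: Iterable[str]) -> None:
        for n in names:
            if n not in self._points:
                raise MissingLandmarkError(n)

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        return LandmarkSet({n: self[n] for n in names})

    def as_array(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self[n] for n in names])

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        return LandmarkSet(
            {n: transform.apply(p[None])[0] for n, p in self._points.items()}
        )

    def translated(self, offset) -> "LandmarkSet":
        off = np.asarray(offset, float).reshape(3)
        return LandmarkSet({n: p + off for n, p in self._points.items()})

    def to_dict(self) -> Dict[str, list]:
        return {n: [float(v) for v in p] for n, p in self._points.items()}

    def __repr__(self):
        return f"LandmarkSet({sorted(self._points)})"


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation then translation)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3))
        if err > 1e-8:
            raise InvalidArgumentError(f"rotation is not orthonormal (|R'R-I|={err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise InvalidArgumentError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise DegenerateInputError("rotation axis must be nonzero")
        axis = axis / n
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def region_counts(labels: np.ndarray) -> Dict[str, int]:
    """Vertex count per region label (including background)."""
    labels = np.asarray(labels, dtype=object)
    out: Dict[str, int] = {}
    for lab in list(REGION_LABELS) + [BACKGROUND]:
        out[lab] = int(np.sum(labels == lab))
    return out
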