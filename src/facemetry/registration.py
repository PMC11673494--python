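"""Rigid registration and deviation analysis.

The evaluation geometry follows clinical surface-scan practice: an
anatomical coordinate frame is built from soft-tissue landmarks (origin
at the midpoint of the bilateral tragion, horizontal plane through the
tragion/infraorbital points, midsagittal plane through the midline
landmarks), a landmark-based rigid pre-alignment seeds a trimmed
point-to-surface ICP "best fit", and deviations are reported as signed
point-to-surface distances, region-wise RMSE, and per-landmark
deviation components along the frame axes.

Distances are measured from the *reconstruction* vertices to the *scan*
surface by default (the scan is the reference surface); the direction is
switchable at the pipeline level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    BACKGROUND,
    DEVIATION_LANDMARKS,
    REGION_LABELS,
    FaceMesh,
    LandmarkSet,
    RigidTransform,
)
from .errors import DegenerateInputError, InvalidArgumentError

DEFAULT_PREALIGN_NAMES = ("ExL", "ExR", "Prn", "N'")
DEFAULT_MIDLINE_NAMES = ("N'", "Prn", "Sn", "Pg'")


# ---------------------------------------------------------------------------
# closed-form rigid alignment
# ---------------------------------------------------------------------------

def kabsch(source: np.ndarray, target: np.ndarray,
           weights: Optional[np.ndarray] = None) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``source`` points onto
    ``target`` points (Kabsch/Horn, no scaling)."""
    P = np.asarray(source, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise InvalidArgumentError("point sets must both be (n, 3)")
    if len(P) < 3:
        raise DegenerateInputError("rigid alignment needs at least 3 points")
    if weights is None:
        weights = np.ones(len(P))
    w = weights / weights.sum()
    cp = w @ P
    cq = w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    if np.linalg.matrix_rank(H, tol=1e-10) < 2:
        raise DegenerateInputError("point configuration is collinear")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def prealign(
    source: LandmarkSet,
    target: LandmarkSet,
    names: Sequence[str] = DEFAULT_PREALIGN_NAMES,
) -> RigidTransform:
    """Closed-form rigid pre-alignment on a small set of matched
    landmarks (default: bilateral exocanthion, pronasale, soft-tissue
    nasion)."""
    source.require(names)
    target.require(names)
    return kabsch(source.as_array(names), target.as_array(names))


# ---------------------------------------------------------------------------
# anatomical coordinate frame
# ---------------------------------------------------------------------------

@dataclass
class AnatomicalFrame:
    """Anatomical coordinate frame: origin (mm) and orthonormal axes
    columns X (subject's left), Y (superior), Z (anterior)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.axes = np.asarray(self.axes, float).reshape(3, 3)
        if np.linalg.norm(self.axes.T @ self.axes - np.eye(3)) > 1e-8:
            raise InvalidArgumentError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise InvalidArgumentError("frame must be right-handed (det +1)")

    def coords(self, points: np.ndarray) -> np.ndarray:
        """World points -> frame coordinates."""
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.origin) @ self.axes

    def direction_coords(self, vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(vectors, float)) @ self.axes


def _ls_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through points."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise DegenerateInputError("plane fit points are collinear or coincident")
    return vt[2]


def build_frame(
    landmarks: LandmarkSet,
    midline_names: Sequence[str] = DEFAULT_MIDLINE_NAMES,
) -> AnatomicalFrame:
    """Anatomical frame from landmarks.

    Origin is the midpoint of the bilateral tragion.  The horizontal
    plane is the least-squares plane through the two tragion and two
    infraorbital landmarks (a soft-tissue Frankfurt-plane proxy); the
    midsagittal plane is the least-squares plane through the midline
    landmarks constrained orthogonal to the horizontal plane.
    """
    for name in ("TraL", "TraR", "OrbL", "OrbR", "Gl"):
        landmarks.require([name])
    landmarks.require(midline_names)
    if len(midline_names) < 3:
        raise InvalidArgumentError("need at least 3 midline landmarks")
    tra_l, tra_r = landmarks["TraL"], landmarks["TraR"]
    if np.linalg.norm(tra_l - tra_r) < 1e-9:
        raise DegenerateInputError("TraL and TraR coincide")
    origin = 0.5 * (tra_l + tra_r)

    horiz_pts = landmarks.as_array(["TraL", "TraR", "OrbL", "OrbR"])
    h = _ls_plane_normal(horiz_pts)
    if h @ (landmarks["Gl"] - origin) < 0:
        h = -h

    # midsagittal normal: constrained orthogonal to the horizontal normal
    mid_pts = landmarks.as_array(midline_names)
    centered = mid_pts - mid_pts.mean(axis=0)
    # basis of the subspace orthogonal to h
    ref = np.array([1.0, 0.0, 0.0])
    if abs(h @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(h, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(h, e1)
    M = centered @ np.stack([e1, e2], axis=1)  # (L, 2)
    _, s2, vt2 = np.linalg.svd(M, full_matrices=False)
    if s2[0] < 1e-9:
        raise DegenerateInputError("midline landmarks coincide")
    v = vt2[1]  # in-plane direction of least spread = sagittal-plane normal
    x = v[0] * e1 + v[1] * e2
    if x @ (tra_l - origin) < 0:
        x = -x

    y = h
    z = np.cross(x, y)
    z /= np.linalg.norm(z)
    if z @ (landmarks["Prn"] - origin) < 0:
        raise DegenerateInputError(
            "frame orientation inconsistent: anterior axis points away from Prn"
        )
    # re-orthonormalize (x is already unit and orthogonal to y up to rounding)
    x = np.cross(y, z)
    x /= np.linalg.norm(x)
    return AnatomicalFrame(origin, np.stack([x, y, z], axis=1))


# ---------------------------------------------------------------------------
# exact point-to-surface distance
# ---------------------------------------------------------------------------

def _point_triangle_closest(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each paired query point.

    ``points`` (m, 3) and ``tri`` (m, 3, 3) are matched row-wise.
    Vectorized form of the standard region-classification algorithm.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    # vertex C
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceDistance:
    """Exact accelerated nearest-point-on-surface queries against a
    triangle mesh.

    A kd-tree over triangle centroids prunes the search: the distance to
    the nearest-centroid triangle gives an upper bound ``u``; any triangle
    holding a closer point must have its centroid within ``u + r_max`` of
    the query (``r_max`` = largest centroid-to-vertex radius), so scanning
    exactly those candidates is exhaustive.  Unlike a k-nearest heuristic
    the result is exact.
    """

    def __init__(self, mesh: FaceMesh):
        if mesh.n_vertices == 0 or len(mesh.faces) == 0:
            raise InvalidArgumentError("target mesh is empty")
        self.mesh = mesh
        self.tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.radii = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.r_max = float(self.radii.max())
        self.tree = cKDTree(self.centroids)
        fn = np.cross(
            self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0]
        )
        norms = np.linalg.norm(fn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.face_normals = fn / norms

    def query(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, unsigned_distances, triangle_index)."""
        points = np.asarray(points, float)
        d_c, nearest = self.tree.query(points)
        # exact distance to the nearest-centroid triangle = upper bound
        cp0 = _point_triangle_closest(points, self.tri[nearest])
        ub = np.linalg.norm(points - cp0, axis=1)

        # the candidate ball always contains the nearest-centroid triangle,
        # so the minimum over candidates is the global minimum
        cand_lists = self.tree.query_ball_point(points, ub + self.r_max)
        counts = np.fromiter((len(c) for c in cand_lists), int, len(points))
        pt_idx = np.repeat(np.arange(len(points)), counts)
        tri_idx = np.fromiter(
            (t for c in cand_lists for t in c), int, int(counts.sum())
        )
        cps = _point_triangle_closest(points[pt_idx], self.tri[tri_idx])
        ds = np.linalg.norm(points[pt_idx] - cps, axis=1)

        best_d = np.full(len(points), np.inf)
        np.minimum.at(best_d, pt_idx, ds)
        achieved = ds <= best_d[pt_idx]
        a_pts, first = np.unique(pt_idx[achieved], return_index=True)
        best_pt = np.empty_like(points)
        best_tri = np.empty(len(points), dtype=int)
        best_pt[a_pts] = cps[achieved][first]
        best_tri[a_pts] = tri_idx[achieved][first]
        return best_pt, best_d, best_tri

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        cp, d, tri = self.query(points)
        offs = np.asarray(points, float) - cp
        sign = np.sign(np.einsum("ij,ij->i", offs, self.face_normals[tri]))
        sign[sign == 0] = 1.0
        return sign * d


def point_to_surface(source: FaceMesh, target: FaceMesh) -> np.ndarray:
    """Signed distance from every source vertex to the nearest point on
    the target surface.  Sign is positive when the source vertex lies on
    the outward (target-normal) side."""
    if source.n_vertices == 0:
        raise InvalidArgumentError("source mesh is empty")
    return SurfaceDistance(target).signed_distances(source.vertices)


# ---------------------------------------------------------------------------
# trimmed ICP best fit
# ---------------------------------------------------------------------------

@dataclass
class IcpConfig:
    """Trimmed point-to-surface ICP settings: keep the best ``trim``
    fraction of correspondences each iteration, stop when the trimmed
    RMSE improves by less than ``tol`` mm."""

    trim: float = 0.9
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self):
        if not (0 < self.trim <= 1):
            raise InvalidArgumentError("trim fraction must be in (0, 1]")


def icp_best_fit(
    source: FaceMesh,
    target: FaceMesh,
    init: Optional[RigidTransform] = None,
    config: Optional[IcpConfig] = None,
) -> Tuple[RigidTransform, List[float]]:
    """Best-fit rigid alignment of ``source`` onto ``target`` by trimmed
    iterative-closest-point with exact point-to-triangle correspondences.

    Returns the transform and the per-iteration trimmed-RMSE trace
    (non-increasing for a fixed trimming set size).
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise InvalidArgumentError("meshes must be non-empty")
    config = config or IcpConfig()
    transform = init or RigidTransform.identity()
    surf = SurfaceDistance(target)
    n_keep = max(3, int(np.ceil(config.trim * source.n_vertices)))

    trace: List[float] = []
    prev = np.inf
    for _ in range(config.max_iter):
        moved = transform.apply(source.vertices)
        cp, d, _ = surf.query(moved)
        keep = np.argsort(d)[:n_keep]
        rmse = float(np.sqrt(np.mean(d[keep] ** 2)))
        trace.append(rmse)
        if prev - rmse < config.tol:
            break
        prev = rmse
        transform = kabsch(source.vertices[keep], cp[keep])
    return transform, trace


# ---------------------------------------------------------------------------
# deviation summaries
# ---------------------------------------------------------------------------

def region_rmse(
    distances: np.ndarray, regions: np.ndarray
) -> Dict[str, float]:
    """RMSE of signed distances per region plus the whole (non-background)
    face under the key ``"face"``.  Empty regions report NaN."""
    distances = np.asarray(distances, float)
    regions = np.asarray(regions, dtype=object)
    if len(distances) != len(regions):
        raise InvalidArgumentError("distances and region map must have equal length")
    out: Dict[str, float] = {}
    nonbg = regions != BACKGROUND
    out["face"] = (
        float(np.sqrt(np.mean(distances[nonbg] ** 2))) if nonbg.any() else float("nan")
    )
    for lab in REGION_LABELS:
        m = regions == lab
        out[lab] = float(np.sqrt(np.mean(distances[m] ** 2))) if m.any() else float("nan")
    return out


def landmark_deviation(
    a: LandmarkSet,
    b: LandmarkSet,
    frame: AnatomicalFrame,
    names: Sequence[str] = DEVIATION_LANDMARKS,
) -> pd.DataFrame:
    """Per-landmark deviation between two landmark sets, decomposed along
    the anatomical frame axes.  Columns D, Dx, Dy, Dz (all mm, all >= 0);
    D is the Euclidean norm of the offset."""
    a.require(names)
    b.require(names)
    rows = []
    for n in names:
        off = frame.direction_coords(b[n] - a[n])[0]
        rows.append(
            {
                "landmark": n,
                "D": float(np.linalg.norm(off)),
                "Dx": float(abs(off[0])),
                "Dy": float(abs(off[1])),
                "Dz": float(abs(off[2])),
            }
        )
    return pd.DataFrame(rows).set_index("landmark")


@dataclass
class DeviationResult:
    """Full deviation analysis of one scan/reconstruction pair."""

    signed_distances: np.ndarray
    region_rmse: Dict[str, float]
    landmark_table: pd.DataFrame
    transform: RigidTransform
    icp_trace: List[float] = field(default_factory=list)

    @property
    def face_rmse(self) -> float:
        return self.region_rmse["face"]


# ---------------------------------------------------------------------------
# color-map export
# ---------------------------------------------------------------------------

def deviation_colors(distances: np.ndarray, range_mm: float = 3.0) -> np.ndarray:
    """Diverging blue-green-red vertex colors for signed distances,
    clamped at ±range_mm (blue = inward, green = zero, red = outward)."""
    if range_mm <= 0:
        raise InvalidArgumentError("range_mm must be > 0")
    d = np.clip(np.asarray(distances, float) / range_mm, -1.0, 1.0)
    t = (d + 1.0) / 2.0  # 0 .. 1
    rgb = np.zeros((len(d), 3))
    lo = t <= 0.5
    u = t[lo] * 2.0
    rgb[lo, 2] = 1.0 - u  # blue fades out
    rgb[lo, 1] = u
    hi = ~lo
    u = (t[hi] - 0.5) * 2.0
    rgb[hi, 1] = 1.0 - u
    rgb[hi, 0] = u
    return np.round(rgb * 255).astype(np.uint8)


def export_colormap(
    mesh: FaceMesh, distances: np.ndarray, path: str, range_mm: float = 3.0
) -> None:
    """Write the mesh as a PLY with per-vertex deviation colors."""
    from .io import write_mesh

    distances = np.asarray(distances, float)
    if len(distances) != mesh.n_vertices:
        raise InvalidArgumentError("distances length must equal vertex count")
    write_mesh(mesh, path, vertex_colors=deviation_colors(distances, range_mm))
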