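"""Linear PCA morphable model of face shape.

A shape is a flattened vertex vector ``s`` (length 3N, mm) expressed as

    s = s_mean + S @ x

with an orthonormal basis ``S`` (3N x k) and dimensionless coefficient
vector ``x``.  The module provides reconstruction, ridge-regression
fitting of the model to named 3D landmarks with alternating closed-form
pose estimation, and the morphable-model augmentation (MMA) procedure:
generating perturbed variants of existing shapes (region swaps, small
rotations, rigid+scale transforms, mirroring) and iteratively growing a
model collection by repeatedly adding the worst-fitting test shape and
recomputing the PCA basis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import FaceMesh, LandmarkSet, RigidTransform
from .errors import DegenerateInputError, InvalidArgumentError
from .registration import kabsch


@dataclass
class MorphableModel:
    """Mean shape plus orthonormal PCA displacement basis.

    Attributes
    ----------
    mean : (3N,) array — average face shape, flattened [x0,y0,z0,x1,...], mm.
    basis : (3N, k) array — orthonormal shape basis columns.
    faces : (m, 3) int array — triangulation shared by all shapes.
    region_labels : optional (N,) array of region label strings.
    landmark_indices : optional mapping landmark name -> vertex index.
    """

    mean: np.ndarray
    basis: np.ndarray
    faces: Optional[np.ndarray] = None
    region_labels: Optional[np.ndarray] = None
    landmark_indices: Optional[Dict[str, int]] = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float).ravel()
        self.basis = np.asarray(self.basis, float)
        if self.basis.ndim != 2 or self.basis.shape[0] != self.mean.size:
            raise InvalidArgumentError("basis must be (3N, k) with 3N = len(mean)")
        if self.mean.size % 3:
            raise InvalidArgumentError("mean length must be a multiple of 3")
        if self.k < 1:
            raise InvalidArgumentError("basis must have at least one column")
        gram_dev = np.abs(self.basis.T @ self.basis - np.eye(self.k)).max()
        if gram_dev > 1e-8:
            raise InvalidArgumentError(
                f"basis columns are not orthonormal (Gram deviation {gram_dev:.2e})"
            )

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.mean.size // 3

    def mean_points(self) -> np.ndarray:
        return self.mean.reshape(-1, 3)

    def shape_to_mesh(self, shape: np.ndarray) -> FaceMesh:
        if self.faces is None:
            raise InvalidArgumentError("model carries no triangulation")
        return FaceMesh(shape.reshape(-1, 3), self.faces,
                        None if self.region_labels is None else self.region_labels.copy())

    def landmarks_of(self, shape: np.ndarray) -> LandmarkSet:
        if not self.landmark_indices:
            raise InvalidArgumentError("model carries no landmark index map")
        pts = shape.reshape(-1, 3)
        return LandmarkSet({n: pts[i] for n, i in self.landmark_indices.items()})


def reconstruct(model: MorphableModel, coeffs: np.ndarray) -> np.ndarray:
    """Shape vector ``mean + basis @ coeffs`` (mm)."""
    coeffs = np.asarray(coeffs, float).ravel()
    if coeffs.size != model.k:
        raise InvalidArgumentError(
            f"coefficient length {coeffs.size} != model k {model.k}"
        )
    return model.mean + model.basis @ coeffs


def project(model: MorphableModel, shape: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of a shape: basis' @ (shape - mean)."""
    shape = np.asarray(shape, float).ravel()
    if shape.size != model.mean.size:
        raise InvalidArgumentError("shape length mismatch")
    return model.basis.T @ (shape - model.mean)


# ---------------------------------------------------------------------------
# ridge landmark fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Settings for the alternating pose/ridge landmark fit.

    ridge_lambda : ridge penalty λ ≥ 0 on the shape coefficients.
    max_iter : alternation budget.
    tol : stop when the landmark RMSE changes by less than this (mm).
    landmark_indices : name -> vertex index map; defaults to the model's.
    """

    ridge_lambda: float = 0.0
    max_iter: int = 50
    tol: float = 1e-6
    landmark_indices: Optional[Dict[str, int]] = None

    def __post_init__(self):
        if self.ridge_lambda < 0:
            raise InvalidArgumentError("ridge penalty must be >= 0")
        if self.tol <= 0:
            raise InvalidArgumentError("tolerance must be > 0")


@dataclass
class FitResult:
    """Outcome of a ridge landmark fit.

    ``l_lan`` is the mean squared 3D landmark distance (mm^2) at the
    solution; ``l_dep`` is its depth (anterior-posterior, model z) share.
    """

    coefficients: np.ndarray
    pose: RigidTransform
    l_lan: float
    l_dep: float
    landmark_rmse: float
    n_iter: int
    converged: bool

    def summary(self) -> str:
        lines = [
            "Ridge landmark fit",
            f"  coefficients       : k={self.coefficients.size}, "
            f"|x|={np.linalg.norm(self.coefficients):.4g}",
            f"  rotation angle     : {np.degrees(self.pose.rotation_angle()):.3f} deg",
            f"  translation        : {np.array2string(self.pose.translation, precision=3)} mm",
            f"  landmark RMSE      : {self.landmark_rmse:.6f} mm",
            f"  L_lan (mean sq)    : {self.l_lan:.6f} mm^2",
            f"  L_dep (depth part) : {self.l_dep:.6f} mm^2",
            f"  iterations         : {self.n_iter} ({'converged' if self.converged else 'budget hit'})",
        ]
        return "\n".join(lines)


def fit_landmarks_ridge(
    model: MorphableModel, targets: LandmarkSet, config: Optional[FitConfig] = None
) -> FitResult:
    """Fit shape coefficients and rigid pose to named 3D landmarks.

    Alternates (a) a closed-form rigid (Kabsch) pose aligning the current
    model landmarks to the targets with (b) the closed-form ridge solution
    ``x = (B'B + λI)^-1 B' r`` on the pose-normalized residual, where B is
    the basis restricted to the mapped landmark rows.  Stops when the
    landmark RMSE changes by less than ``config.tol``.
    """
    config = config or FitConfig()
    index_map = config.landmark_indices or model.landmark_indices
    if not index_map:
        raise InvalidArgumentError("no landmark-to-vertex index map available")
    names = [n for n in index_map if n in targets]
    if len(names) < 4:
        raise DegenerateInputError(
            f"need at least 4 mapped landmarks, got {len(names)}"
        )
    T = targets.as_array(names)  # (L, 3)
    centered = T - T.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise DegenerateInputError("landmark configuration is coplanar")

    idx = np.array([index_map[n] for n in names])
    rows = np.stack([3 * idx, 3 * idx + 1, 3 * idx + 2], axis=1).ravel()
    mean_l = model.mean[rows].reshape(-1, 3)
    B = model.basis[rows, :]  # (3L, k)
    lam = config.ridge_lambda
    lhs = B.T @ B + lam * np.eye(model.k)

    x = np.zeros(model.k)
    pose = RigidTransform.identity()
    prev_rmse = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        pts = mean_l + (B @ x).reshape(-1, 3)
        pose = kabsch(pts, T)
        # pose-normalized targets: bring targets into the model frame
        T_model = (T - pose.translation) @ pose.rotation
        r = (T_model - mean_l).ravel()
        x = np.linalg.solve(lhs, B.T @ r)
        pts = mean_l + (B @ x).reshape(-1, 3)
        diff = pose.apply(pts) - T
        rmse = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
        if abs(prev_rmse - rmse) < config.tol:
            converged = True
            break
        prev_rmse = rmse

    # losses at the solution, residual expressed in the model frame so the
    # depth share is along the model's anterior (z) axis
    diff_model = (T - pose.translation) @ pose.rotation - pts
    l_lan = float(np.mean(np.sum(diff_model**2, axis=1)))
    l_dep = float(np.mean(diff_model[:, 2] ** 2))
    return FitResult(
        coefficients=x,
        pose=pose,
        l_lan=l_lan,
        l_dep=l_dep,
        landmark_rmse=float(np.sqrt(np.mean(np.sum((pose.apply(pts) - T) ** 2, axis=1)))),
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# morphable model augmentation (MMA)
# ---------------------------------------------------------------------------

@dataclass
class PerturbConfig:
    """Which augmentation operations to apply and their magnitudes.

    Each enabled operation produces one extra variant per input shape;
    the original is always retained, so the output size is
    ``len(inputs) * (n_enabled + 1)``.
    """

    swap_nose: bool = True
    swap_mouth: bool = True
    rotate: bool = True
    rotate_sd_deg: float = 3.0
    rigid_scale: bool = True
    translation_sd_mm: float = 5.0
    scale_sd: float = 0.03
    mirror: bool = True
    blend_band_mm: float = 2.0

    def enabled_ops(self) -> List[str]:
        ops = []
        if self.swap_nose:
            ops.append("swap_nose")
        if self.swap_mouth:
            ops.append("swap_mouth")
        if self.rotate:
            ops.append("rotate")
        if self.rigid_scale:
            ops.append("rigid_scale")
        if self.mirror:
            ops.append("mirror")
        return ops


def _region_blend_weights(
    points: np.ndarray, labels: np.ndarray, region: Sequence[str], band: float
) -> np.ndarray:
    """Per-vertex blend weight: 1 deep inside the region, feathered
    linearly to 0 over ``band`` mm near the region boundary."""
    inside = np.isin(labels.astype(str), list(region))
    if not inside.any() or inside.all():
        return inside.astype(float)
    tree = cKDTree(points[~inside])
    d, _ = tree.query(points[inside])
    w = np.zeros(len(points))
    w[inside] = np.clip(d / band, 0.0, 1.0)
    return w


def mirror_index_map(points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Vertex index map pairing each vertex with its midsagittal mirror
    (x -> -x).  Requires a mirror-symmetric vertex set."""
    reflected = points.copy()
    reflected[:, 0] *= -1
    tree = cKDTree(points)
    d, idx = tree.query(reflected)
    if d.max() > tol:
        raise DegenerateInputError(
            f"vertex set is not mirror-symmetric (max pairing error {d.max():.3g} mm)"
        )
    return idx


def mirror_shape(shape: np.ndarray, index_map: np.ndarray) -> np.ndarray:
    """Mirror a shape vector about the midsagittal plane using a
    precomputed symmetric vertex pairing; an involution."""
    pts = shape.reshape(-1, 3)[index_map].copy()
    pts[:, 0] *= -1
    return pts.ravel()


def mma_perturb(
    models: Sequence[np.ndarray],
    base: MorphableModel,
    ops: Optional[PerturbConfig] = None,
    seed: int = 0,
) -> List[np.ndarray]:
    """Generate augmented shape variants: nose/mouth region swaps from
    donor shapes (feather-blended at the region boundary), small rotation
    perturbations, random rigid+scale transforms, and midsagittal mirrors."""
    ops = ops or PerturbConfig()
    enabled = ops.enabled_ops()
    if ("swap_nose" in enabled or "swap_mouth" in enabled) and base.region_labels is None:
        raise InvalidArgumentError("region swaps require region labels on the base model")
    rng = np.random.default_rng(seed)
    models = [np.asarray(m, float).ravel() for m in models]
    base_pts = model_points = base.mean_points()

    weights: Dict[str, np.ndarray] = {}
    if "swap_nose" in enabled:
        weights["swap_nose"] = _region_blend_weights(
            base_pts, base.region_labels, ["nose"], ops.blend_band_mm
        )
    if "swap_mouth" in enabled:
        weights["swap_mouth"] = _region_blend_weights(
            base_pts, base.region_labels, ["upper_lip", "lower_lip"], ops.blend_band_mm
        )
    if "mirror" in enabled:
        # pair vertices on the transverse chart (x, y): the template grid is
        # exactly mirror-symmetric there even when the surface height carries
        # a small asymmetry field
        chart = model_points.copy()
        chart[:, 2] = 0.0
        mir = mirror_index_map(chart)
    else:
        mir = None

    out: List[np.ndarray] = []
    for i, m in enumerate(models):
        out.append(m.copy())
        for op in enabled:
            if op in ("swap_nose", "swap_mouth"):
                donor_i = int(rng.integers(len(models)))
                donor = models[donor_i]
                w = np.repeat(weights[op], 3)
                out.append(m * (1 - w) + donor * w)
            elif op == "rotate":
                angle = rng.normal(0.0, np.radians(ops.rotate_sd_deg))
                axis = rng.normal(size=3)
                pts = m.reshape(-1, 3)
                c = pts.mean(axis=0)
                if abs(angle) < 1e-15:
                    out.append(m.copy())
                else:
                    R = RigidTransform.from_axis_angle(axis, angle).rotation
                    out.append(((pts - c) @ R.T + c).ravel())
            elif op == "rigid_scale":
                angle = rng.normal(0.0, np.radians(ops.rotate_sd_deg))
                axis = rng.normal(size=3)
                t = rng.normal(0.0, ops.translation_sd_mm, size=3)
                s = abs(1.0 + rng.normal(0.0, ops.scale_sd))
                pts = m.reshape(-1, 3)
                c = pts.mean(axis=0)
                if abs(angle) < 1e-15:
                    R = np.eye(3)
                else:
                    R = RigidTransform.from_axis_angle(axis, angle).rotation
                out.append((s * (pts - c) @ R.T + c + t).ravel())
            elif op == "mirror":
                out.append(mirror_shape(m, mir))
    return out


def _pca_basis(collection: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and top-k orthonormal PCA basis of a stack of shape vectors."""
    mean = collection.mean(axis=0)
    centered = collection - mean
    max_k = min(centered.shape) - 1 if len(collection) > 1 else 1
    max_k = max(max_k, 1)
    if k > max_k:
        warnings.warn(
            f"requested k={k} exceeds collection capacity {max_k}; basis truncated",
            RuntimeWarning,
        )
        k = max_k
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    return mean, vt[:k].T


def _align_to_model(
    shape: np.ndarray, mean: np.ndarray, basis: np.ndarray,
    max_iter: int = 30, tol: float = 1e-10,
) -> np.ndarray:
    """Rigidly normalize a shape against a model by alternating a Kabsch
    pose with a λ=0 basis projection; returns the aligned shape vector.

    Starts from the better of the identity pose and the Kabsch alignment
    to the model mean, so a shape the model represents exactly (e.g. a
    collection member under a spanning basis) keeps a zero residual.
    """
    pts = shape.reshape(-1, 3)

    def resid_norm(aligned: np.ndarray) -> float:
        r = aligned - mean
        return float(np.linalg.norm(r - basis @ (basis.T @ r)))

    start_identity = shape
    start_kabsch = kabsch(pts, mean.reshape(-1, 3)).apply(pts).ravel()
    aligned = min((start_identity, start_kabsch), key=resid_norm)
    prev = resid_norm(aligned)
    for _ in range(max_iter):
        r = aligned - mean
        fitted = mean + basis @ (basis.T @ r)
        pose = kabsch(pts, fitted.reshape(-1, 3))
        candidate = pose.apply(pts).ravel()
        err = resid_norm(candidate)
        if err > prev - tol:
            break
        aligned = candidate
        prev = err
    return aligned


def _fit_error(shape: np.ndarray, mean: np.ndarray, basis: np.ndarray) -> float:
    """RMS per-vertex residual of a λ=0 projection after rigid alignment."""
    aligned = _align_to_model(shape, mean, basis)
    r = aligned - mean
    resid = r - basis @ (basis.T @ r)
    return float(np.sqrt(np.mean(np.sum(resid.reshape(-1, 3) ** 2, axis=1))))


def mma_construct(
    generated: Sequence[np.ndarray],
    k: int,
    n_outer: int = 1,
    test_fraction: float = 0.5,
    seed: int = 0,
    n_inner: int = 5,
    initial_size: Optional[int] = None,
    base: Optional[MorphableModel] = None,
) -> Tuple[MorphableModel, List[List[float]]]:
    """Iterative PCA-basis construction on an augmented shape set.

    Outer loop: draw a random test subset of the generated shapes.
    Inner loop: fit the current model to each test shape (rigid alignment
    followed by a λ=0 basis projection), append the worst-fitting shape to
    the collection, recompute the k-component PCA basis.  Returns the
    final model and the per-inner-iteration max test error trace, one list
    per outer round.

    The rigid normalization of each test shape is computed once per outer
    round, against the model state the round starts from, and held fixed
    across the inner iterations.  The fit error is then exactly the
    distance of the normalized shape to the affine hull of the collection,
    which only grows as shapes are appended — so whenever the basis spans
    the collection (k >= collection size - 1) the max-error trace is
    non-increasing by construction.
    """
    if not (0 < test_fraction <= 1):
        raise InvalidArgumentError("test_fraction must be in (0, 1]")
    generated = [np.asarray(g, float).ravel() for g in generated]
    initial_size = initial_size if initial_size is not None else min(k + 1, len(generated) - 1)
    if initial_size < 2 or len(generated) <= initial_size:
        raise InvalidArgumentError(
            "generated set must be larger than the initial collection"
        )
    rng = np.random.default_rng(seed)

    collection_idx = list(range(initial_size))
    mean, basis = _pca_basis(np.array([generated[i] for i in collection_idx]), k)

    def proj_error(aligned: np.ndarray) -> float:
        r = aligned - mean
        resid = r - basis @ (basis.T @ r)
        return float(np.sqrt(np.mean(np.sum(resid.reshape(-1, 3) ** 2, axis=1))))

    traces: List[List[float]] = []
    for _ in range(n_outer):
        n_test = max(1, int(round(test_fraction * len(generated))))
        test_idx = rng.choice(len(generated), size=n_test, replace=False)
        aligned = {int(i): _align_to_model(generated[i], mean, basis) for i in test_idx}
        trace: List[float] = []
        for _ in range(n_inner):
            errors = np.array([proj_error(aligned[int(i)]) for i in test_idx])
            trace.append(float(errors.max()))
            candidates = [
                (e, i) for e, i in zip(errors, test_idx) if i not in collection_idx
            ]
            if not candidates:
                break
            _, worst = max(candidates, key=lambda t: t[0])
            collection_idx.append(int(worst))
            mean, basis = _pca_basis(
                np.array([generated[i] for i in collection_idx]), k
            )
        # error of the final recomputed model on the same test set
        errors = np.array([proj_error(aligned[int(i)]) for i in test_idx])
        trace.append(float(errors.max()))
        traces.append(trace)

    model = MorphableModel(
        mean=mean,
        basis=basis,
        faces=None if base is None else base.faces,
        region_labels=None if base is None else base.region_labels,
        landmark_indices=None if base is None else base.landmark_indices,
    )
    return model, traces


# ---------------------------------------------------------------------------
# model archive IO: .npz container + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: MorphableModel, path: str, metadata: Optional[dict] = None) -> None:
    """Save a model as a .npz archive with a human-readable JSON sidecar
    recording k, vertex count and any caller-supplied provenance."""
    arrays = {"mean": model.mean, "basis": model.basis}
    if model.faces is not None:
        arrays["faces"] = model.faces
    if model.region_labels is not None:
        arrays["region_labels"] = model.region_labels.astype(str)
    if model.landmark_indices:
        names = sorted(model.landmark_indices)
        arrays["landmark_names"] = np.array(names)
        arrays["landmark_vertex"] = np.array([model.landmark_indices[n] for n in names])
    np.savez(path, **arrays)
    side = {"k": model.k, "n_vertices": model.n_vertices}
    side.update(metadata or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=1)
        fh.write("\n")


def load_model(path: str) -> MorphableModel:
    with np.load(path, allow_pickle=False) as data:
        lm = None
        if "landmark_names" in data:
            lm = {
                str(n): int(i)
                for n, i in zip(data["landmark_names"], data["landmark_vertex"])
            }
        return MorphableModel(
            mean=data["mean"],
            basis=data["basis"],
            faces=data["faces"] if "faces" in data else None,
            region_labels=data["region_labels"].astype(object)
            if "region_labels" in data
            else None,
            landmark_indices=lm,
        )
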