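"""Landmark-based rigid registration by SVD least squares.

Given paired point sets :math:`L_{model}` and :math:`L_{patient}` the
solver finds the rotation ``R`` and translation ``T`` minimising

.. math:: \\sum_i \\| L_{patient,i} - (R \\cdot L_{model,i} + T) \\|_2^2

by the classical closed form: center both sets on their centroids, form
the 3x3 cross-covariance ``H``, take its SVD ``H = U S Vt``, and set
``R = V @ U.T`` with a sign correction on the smallest singular
direction when ``det(V @ U.T) = -1`` (which would otherwise return a
reflection).  ``T`` then aligns the centroids.  The solution is the
global minimiser over all proper rigid transforms.

The module also carries two independent diagnostics: an exhaustive
Euler-grid search used as a verification oracle, and the closed-form
expected target registration error (TRE) for isotropic fiducial
localization error (FLE), used to validate noise simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, ParameterError
from .landmarks import LandmarkSet

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "estimate_rigid_transform",
    "apply_transform",
    "alignment_objective",
    "brute_force_oracle",
    "expected_tre",
]

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """A proper rigid motion ``p -> R @ p + T`` in millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ParameterError("rigid transform needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ParameterError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ParameterError("rotation matrix has det -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, angles_deg, translation, order: str = "xyz") -> "RigidTransform":
        rot = Rotation.from_euler(order, np.asarray(angles_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def save_json(self, path: str | Path, **meta) -> None:
        payload = {"matrix": self.matrix.tolist(), **meta}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "RigidTransform":
        m = np.asarray(json.loads(Path(path).read_text())["matrix"], dtype=float)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class RegistrationResult:
    """The fitted transform plus every intermediate of the closed form."""

    transform: RigidTransform
    centroid_model: np.ndarray
    centroid_patient: np.ndarray
    covariance_H: np.ndarray
    svd_U: np.ndarray
    svd_S: np.ndarray
    svd_Vt: np.ndarray
    per_landmark_residual: np.ndarray
    fre_rms: float
    reflection_corrected: bool
    landmark_names: list[str] = field(default_factory=list)

    @property
    def objective(self) -> float:
        """Sum of squared residuals (the least-squares objective value)."""
        return float(np.sum(self.per_landmark_residual**2))

    def save_json(self, path: str | Path) -> None:
        self.transform.save_json(
            path,
            fre_rms=self.fre_rms,
            reflection_corrected=self.reflection_corrected,
            landmark_names=self.landmark_names,
            per_landmark_residual=self.per_landmark_residual.tolist(),
        )


def _as_points(obj) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(obj, LandmarkSet):
        return obj.points, obj.names
    pts = np.atleast_2d(np.asarray(obj, dtype=float))
    if pts.shape[1] != 3:
        raise ParameterError(f"expected Nx3 points, got shape {pts.shape}")
    return pts, None


def estimate_rigid_transform(model, patient) -> RegistrationResult:
    """Fit the optimal proper rigid transform mapping model landmarks onto patient landmarks.

    Parameters
    ----------
    model, patient:
        Paired :class:`LandmarkSet` objects (names checked for identical
        order), or plain ``(n, 3)`` arrays assumed index-paired. ``n >= 3``
        and the points must not be collinear.

    Raises
    ------
    PairingError
        If lengths or name order differ.
    DegenerateInputError
        If the landmark configuration is (near-)collinear, i.e.
        ``rank(H) < 2`` by singular-value ratio.
    """
    if isinstance(model, LandmarkSet) and isinstance(patient, LandmarkSet):
        model.check_paired_with(patient)
    p, names = _as_points(model)
    q, _ = _as_points(patient)
    if p.shape != q.shape:
        raise ParameterError(f"point set shapes differ: {p.shape} vs {q.shape}")
    n = p.shape[0]
    if n < 3:
        raise DegenerateInputError(f"registration needs >= 3 landmarks, got {n}")

    centroid_model = p.mean(axis=0)
    centroid_patient = q.mean(axis=0)
    pc = p - centroid_model
    qc = q - centroid_patient

    # Collinearity: the centered model points must span a plane.
    config_sv = np.linalg.svd(pc, compute_uv=False)
    if config_sv[0] <= 0 or config_sv[1] / config_sv[0] < _ORTHO_TOL:
        raise DegenerateInputError("landmarks are collinear or coincident; rigid fit is underdetermined")

    H = pc.T @ qc
    U, S, Vt = np.linalg.svd(H)
    d = np.linalg.det(Vt.T @ U.T)
    reflection_corrected = d < 0
    # Sign flip on the smallest singular direction keeps det(R) = +1.
    D = np.diag([1.0, 1.0, float(np.sign(d))])
    R = Vt.T @ D @ U.T
    T = centroid_patient - R @ centroid_model

    transform = RigidTransform(R, T)
    residuals = np.linalg.norm(q - transform.apply(p), axis=1)
    fre_rms = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(
        transform=transform,
        centroid_model=centroid_model,
        centroid_patient=centroid_patient,
        covariance_H=H,
        svd_U=U,
        svd_S=S,
        svd_Vt=Vt,
        per_landmark_residual=residuals,
        fre_rms=fre_rms,
        reflection_corrected=bool(reflection_corrected),
        landmark_names=list(names) if names else [],
    )


def alignment_objective(transform: RigidTransform, model, patient) -> float:
    """Sum of squared distances after applying ``transform`` to the model points."""
    p, _ = _as_points(model)
    q, _ = _as_points(patient)
    return float(np.sum((q - transform.apply(p)) ** 2))


def apply_transform(transform: RigidTransform, target):
    """Apply a rigid transform to points, a LandmarkSet, or a surface mesh.

    Mesh topology (faces) is untouched; only vertex coordinates move.
    """
    from .meshing import SurfaceMesh  # local import; meshing depends on nothing here

    if isinstance(target, LandmarkSet):
        return target.with_points(transform.apply(target.points))
    if isinstance(target, SurfaceMesh):
        return SurfaceMesh(transform.apply(target.vertices), target.faces.copy(), target.name)
    return transform.apply(np.asarray(target, dtype=float))


def _iter_rotation_chunks(angle_step_deg: float):
    """Yield stacked rotation matrices covering SO(3) on a z-y-x Euler grid.

    Chunked by the first Euler angle so a fine grid never materialises at
    once (a 1-degree grid holds ~23.5M rotations).
    """
    a_vals = np.arange(0.0, 360.0, angle_step_deg)
    b = np.arange(-90.0, 90.0 + 1e-9, angle_step_deg)
    c = np.arange(0.0, 360.0, angle_step_deg)
    bc = np.stack(np.meshgrid(b, c, indexing="ij"), axis=-1).reshape(-1, 2)
    grid = np.empty((bc.shape[0], 3))
    grid[:, 1:] = bc
    for a in a_vals:
        grid[:, 0] = a
        yield Rotation.from_euler("zyx", grid, degrees=True).as_matrix()


def brute_force_oracle(model, patient, angle_step: float = 2.0) -> RigidTransform:
    """Exhaustively search an Euler-angle grid for the best rigid alignment.

    Independent verification oracle for :func:`estimate_rigid_transform`:
    for each grid rotation the translation is set optimally (centroid
    alignment), and the grid minimiser of the least-squares objective is
    returned.  Deliberately avoids the SVD closed form.
    """
    if angle_step > 5.0:
        raise ParameterError("oracle angle_step must be <= 5 degrees")
    p, _ = _as_points(model)
    q, _ = _as_points(patient)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    # With centroid-optimal translation the objective is
    # ||qc||^2 + ||pc||^2 - 2 tr(R @ H) with H = pc.T @ qc; maximise tr(R @ H).
    H = pc.T @ qc
    best_trace = -np.inf
    best_R = np.eye(3)
    for rots in _iter_rotation_chunks(angle_step):
        traces = np.einsum("nij,ji->n", rots, H)
        i = int(np.argmax(traces))
        if traces[i] > best_trace:
            best_trace = float(traces[i])
            best_R = rots[i].copy()
    T = q.mean(axis=0) - best_R @ p.mean(axis=0)
    return RigidTransform(best_R, T)


def expected_tre(landmarks, target, fle_rms: float) -> float:
    """Closed-form expected RMS target registration error.

    Implements the standard first-order approximation for point-based
    rigid registration with identical, independent, isotropic FLE:

    .. math:: TRE^2(r) \\approx \\frac{FLE^2}{n}\\left(1 + \\frac{1}{3}
              \\sum_{k=1}^{3} \\frac{d_k^2}{f_k^2}\\right)

    where ``d_k`` is the distance of the target from principal axis ``k``
    of the landmark configuration and ``f_k`` the RMS distance of the
    landmarks from that axis.
    """
    if fle_rms <= 0:
        raise ParameterError("fle_rms must be positive")
    p, _ = _as_points(landmarks)
    n = p.shape[0]
    if n < 3:
        raise DegenerateInputError("expected_tre needs >= 3 landmarks")
    target = np.asarray(target, dtype=float)
    centroid = p.mean(axis=0)
    pc = p - centroid
    config_sv = np.linalg.svd(pc, compute_uv=False)
    if config_sv[0] <= 0 or config_sv[1] / config_sv[0] < _ORTHO_TOL:
        raise DegenerateInputError("landmark configuration is degenerate")
    # Principal axes of the configuration (unit vectors through the centroid).
    _, _, axes = np.linalg.svd(pc)
    rel = target - centroid
    ratio = 0.0
    for k in range(3):
        axis = axes[k]
        # Squared distance from a line through the centroid with direction `axis`.
        d2 = float(np.sum(rel**2) - np.dot(rel, axis) ** 2)
        f2 = float(np.mean(np.sum(pc**2, axis=1) - (pc @ axis) ** 2))
        ratio += d2 / f2
    return float(np.sqrt(fle_rms**2 / n * (1.0 + ratio / 3.0)))
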