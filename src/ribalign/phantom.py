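"""Synthetic torso phantom: CT-like volumes, bony landmarks, rib fractures, pose change.

The phantom stands in for the physical studies' inputs: an ellipsoidal
soft-tissue torso with embedded rib-shaped bone tubes, an optional
scanner-bed slab beneath it, named bony landmarks at fixed parametric
sites on the skin, fracture sites sampled on rib centerlines, and a
seeded scan-to-operating-room pose change (smooth bend + rigid motion +
per-landmark localization noise).

World frame is RAS: +x patient right, +y anterior, +z superior, torso
centred at the origin.  Default outer dimensions follow a human torso
mannequin of 390 x 224 x 670 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import CapacityError, ParameterError, SizingError, UnknownLandmarkError
from .landmarks import FracturePoint, LandmarkSet
from .registration import RigidTransform
from .volume import Mask, Volume

__all__ = [
    "CANDIDATE_LANDMARKS",
    "LABELS",
    "PhantomSpec",
    "DeformationSpec",
    "generate_labels",
    "generate_torso_volume",
    "label_mask",
    "place_landmarks",
    "place_fractures",
    "simulate_pose_change",
]

# Integer codes of the construction-time label grid.
LABELS = {"air": 0, "soft_tissue": 1, "bone": 2, "bed": 3}

# Parametric skin sites of the ten candidate bony landmarks.  Each entry
# is (u, w, anterior): the surface point is (a*u, +-b*v, c*w) with
# v = sqrt(1 - u^2 - w^2), positive v anterior.  u is the left-right
# fraction (+x = patient right), w the inferior-superior fraction.
# The names follow the candidate list used for model-patient alignment
# (suprasternal notch, acromioclavicular joints, xiphisternum, ASIS,
# C7/T1, PSIS); the coordinates are this package's fixed convention.
_LANDMARK_SITES: dict[str, tuple[float, float, bool]] = {
    "suprasternal_notch": (0.00, 0.60, True),
    "left_ac_joint": (-0.55, 0.70, True),
    "right_ac_joint": (0.55, 0.70, True),
    "xiphisternum": (0.00, 0.25, True),
    "left_asis": (-0.45, -0.75, True),
    "right_asis": (0.45, -0.75, True),
    "c7": (0.00, 0.80, False),
    "t1": (0.00, 0.72, False),
    "left_psis": (-0.30, -0.70, False),
    "right_psis": (0.30, -0.70, False),
}

CANDIDATE_LANDMARKS = tuple(_LANDMARK_SITES)

# Rib band placement, as fractions of the torso half-axes: ribs occupy
# z/c in [-0.25, 0.55], lie at 0.88 of the local cross-section (about
# 12 mm under the skin for the default torso), and leave azimuthal gaps
# at the sternum and the spine.
_RIB_Z_TOP = 0.55
_RIB_Z_BOTTOM = -0.25
_RIB_SURFACE_FRACTION = 0.88
_RIB_GAP_STERNUM_DEG = 14.0
_RIB_GAP_SPINE_DEG = 14.0

_BED_GAP_MM = 8.0
_BED_THICKNESS_MM = 20.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic torso phantom.

    ``torso_half_axes`` are the ellipsoid semi-axes (x, y, z) in mm;
    defaults reproduce a 390 x 224 x 670 mm torso mannequin.  HU values
    must be ordered air < soft tissue < bone.  ``grid_shape`` may pin
    the voxel grid explicitly; by default it is sized to contain the
    torso (and bed) with a small air margin.
    """

    torso_half_axes: tuple[float, float, float] = (195.0, 112.0, 335.0)
    n_rib_pairs: int = 8
    rib_tube_radius: float = 6.0
    landmark_names: tuple[str, ...] = (
        "suprasternal_notch",
        "left_ac_joint",
        "right_ac_joint",
        "xiphisternum",
        "c7",
    )
    bed_enabled: bool = True
    hu_air: float = -1000.0
    hu_soft_tissue: float = 40.0
    hu_bone: float = 700.0
    hu_bed: float = 300.0
    noise_sd: float = 15.0
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    margin_mm: float = 10.0
    grid_shape: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        half = np.asarray(self.torso_half_axes, dtype=float)
        spacing = np.asarray(self.voxel_spacing, dtype=float)
        if half.shape != (3,) or np.any(half <= 0):
            raise ParameterError(f"torso_half_axes must be 3 positive lengths, got {self.torso_half_axes}")
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ParameterError(f"voxel_spacing must be 3 positive lengths, got {self.voxel_spacing}")
        if self.rib_tube_radius <= 0:
            raise ParameterError("rib_tube_radius must be positive")
        if self.n_rib_pairs < 0:
            raise ParameterError("n_rib_pairs must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        names = tuple(self.landmark_names)
        if not (3 <= len(names) <= 10):
            raise ParameterError(f"landmark_names needs 3-10 entries, got {len(names)}")
        if len(set(names)) != len(names):
            raise ParameterError("landmark_names must be distinct")
        for n in names:
            if n not in _LANDMARK_SITES:
                raise UnknownLandmarkError(
                    f"unknown landmark {n!r}; candidates: {sorted(_LANDMARK_SITES)}"
                )
        if not (self.hu_air < self.hu_soft_tissue < self.hu_bone):
            raise ParameterError("HU ordering must satisfy air < soft tissue < bone")
        object.__setattr__(self, "landmark_names", names)

    # ------------------------------------------------------------- geometry
    @property
    def half_axes(self) -> np.ndarray:
        return np.asarray(self.torso_half_axes, dtype=float)

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.voxel_spacing, dtype=float)

    def grid_geometry(self) -> tuple[tuple[int, int, int], np.ndarray]:
        """Return (shape, origin) of the voxel grid, validating containment."""
        half = self.half_axes
        lo = -(half + self.margin_mm)
        hi = half + self.margin_mm
        if self.bed_enabled:
            lo[1] = -(half[1] + _BED_GAP_MM + _BED_THICKNESS_MM + self.margin_mm)
        if self.grid_shape is None:
            shape = tuple(int(np.ceil((hi[a] - lo[a]) / self.spacing[a])) + 1 for a in range(3))
        else:
            shape = tuple(int(s) for s in self.grid_shape)
            for a, axis_name in enumerate("xyz"):
                if (shape[a] - 1) * self.spacing[a] < hi[a] - lo[a]:
                    raise SizingError(
                        f"grid too small along {axis_name}: needs "
                        f"{(hi[a] - lo[a]) / self.spacing[a] + 1:.0f} voxels, has {shape[a]}"
                    )
        return shape, lo

    def rib_z_fractions(self) -> np.ndarray:
        """Superior-to-inferior z/c fractions of the rib pair centerplanes."""
        if self.n_rib_pairs == 0:
            return np.empty(0)
        if self.n_rib_pairs == 1:
            return np.array([(_RIB_Z_TOP + _RIB_Z_BOTTOM) / 2.0])
        return np.linspace(_RIB_Z_TOP, _RIB_Z_BOTTOM, self.n_rib_pairs)

    def rib_centerline(self, rib_index: int, side: str, arc_step_mm: float = 1.0) -> np.ndarray:
        """Densely sampled centerline points (mm) of one rib.

        The rib is an elliptical arc in the plane z = w*c, following the
        torso cross-section at ``_RIB_SURFACE_FRACTION`` of its local
        semi-axes.  ``side`` is "left" (patient left, -x) or "right".
        """
        if side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
        w = self.rib_z_fractions()[rib_index]
        a, b, c = self.half_axes
        s = _RIB_SURFACE_FRACTION * np.sqrt(max(1.0 - w * w, 0.0))
        az, bz = a * s, b * s
        # phi measured from anterior midline (+y); patient right is +x.
        phi0 = np.deg2rad(_RIB_GAP_STERNUM_DEG)
        phi1 = np.pi - np.deg2rad(_RIB_GAP_SPINE_DEG)
        # Arc length upper bound for sampling density.
        n_samples = max(int(np.ceil(max(az, bz) * (phi1 - phi0) / arc_step_mm)), 8)
        phi = np.linspace(phi0, phi1, n_samples)
        sign = 1.0 if side == "right" else -1.0
        return np.column_stack(
            [sign * az * np.sin(phi), bz * np.cos(phi), np.full_like(phi, w * c)]
        )


@dataclass
class DeformationSpec:
    """Scan-to-OR pose change: smooth bend, rigid motion, landmark noise.

    ``bend_amplitude`` scales a low-frequency single-axis sinusoidal bend
    plus a linear shear (max per-axis displacement = amplitude, zero at
    zero amplitude), emulating the supine to lateral-decubitus torso
    deformation.  ``landmark_noise_sd`` is the per-axis standard
    deviation (mm) of the isotropic Gaussian localization error added to
    patient-side landmarks, emulating fiducial-marker placement and
    detection error.
    """

    rigid_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rigid_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bend_amplitude: float = 0.0
    landmark_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_noise_sd < 0:
            raise ParameterError("landmark_noise_sd must be >= 0")
        if self.bend_amplitude < 0:
            raise ParameterError("bend_amplitude must be >= 0")

    def rigid(self) -> RigidTransform:
        return RigidTransform.from_euler(self.rigid_rotation, self.rigid_translation)


# ---------------------------------------------------------------------------
# Volume generation
# ---------------------------------------------------------------------------

def generate_labels(spec: PhantomSpec) -> Volume:
    """Construction-time label grid (codes in :data:`LABELS`) for a spec.

    This is the ground truth that segmentation results are judged
    against; :func:`generate_torso_volume` derives its HU values from it.
    """
    shape, origin = spec.grid_geometry()
    spacing = spec.spacing
    a, b, c = spec.half_axes

    x = origin[0] + np.arange(shape[0]) * spacing[0]
    y = origin[1] + np.arange(shape[1]) * spacing[1]
    z = origin[2] + np.arange(shape[2]) * spacing[2]

    labels = np.zeros(shape, dtype=np.int8)
    ellip = (
        (x[:, None, None] / a) ** 2
        + (y[None, :, None] / b) ** 2
        + (z[None, None, :] / c) ** 2
    ) <= 1.0
    labels[ellip] = LABELS["soft_tissue"]

    for i in range(spec.n_rib_pairs):
        for side in ("left", "right"):
            line = spec.rib_centerline(i, side)
            tree = cKDTree(line)
            lo = line.min(axis=0) - spec.rib_tube_radius - spacing
            hi = line.max(axis=0) + spec.rib_tube_radius + spacing
            i0 = np.maximum(np.searchsorted(x, lo[0]), 0)
            i1 = np.searchsorted(x, hi[0])
            j0 = np.maximum(np.searchsorted(y, lo[1]), 0)
            j1 = np.searchsorted(y, hi[1])
            k0 = np.maximum(np.searchsorted(z, lo[2]), 0)
            k1 = np.searchsorted(z, hi[2])
            gx, gy, gz = np.meshgrid(x[i0:i1], y[j0:j1], z[k0:k1], indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            dist, _ = tree.query(pts, k=1)
            inside = (dist <= spec.rib_tube_radius).reshape(gx.shape)
            sub = labels[i0:i1, j0:j1, k0:k1]
            sub[inside] = LABELS["bone"]

    if spec.bed_enabled:
        bed_top = -(b + _BED_GAP_MM)
        bed_bottom = bed_top - _BED_THICKNESS_MM
        jsel = (y >= bed_bottom) & (y <= bed_top)
        # Bed slab spans the grid in x and z, one voxel in from the border.
        labels[1:-1, jsel, 1:-1] = LABELS["bed"]

    return Volume(
        data=labels,
        spacing=spacing.copy(),
        origin=origin.copy(),
        meta={"labels": dict(LABELS), "kind": "phantom-labels"},
    )


def label_mask(labels: Volume, name: str) -> Mask:
    """Binary mask of one label class of a label grid."""
    return Mask.like(labels, labels.data == LABELS[name], label=name)


def generate_torso_volume(spec: PhantomSpec) -> Volume:
    """CT-like HU volume of the phantom; bit-identical for identical spec."""
    labels = generate_labels(spec)
    hu = np.empty(labels.shape, dtype=float)
    hu[...] = spec.hu_air
    hu[labels.data == LABELS["soft_tissue"]] = spec.hu_soft_tissue
    hu[labels.data == LABELS["bone"]] = spec.hu_bone
    hu[labels.data == LABELS["bed"]] = spec.hu_bed
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, size=hu.shape)
    return Volume(
        data=hu,
        spacing=labels.spacing,
        origin=labels.origin,
        meta={"kind": "phantom-ct", "noise_sd": spec.noise_sd, "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# Landmarks and fractures
# ---------------------------------------------------------------------------

def place_landmarks(spec: PhantomSpec, names: tuple[str, ...] | None = None) -> LandmarkSet:
    """Model-frame landmark set at the spec's parametric skin sites."""
    names = tuple(names) if names is not None else spec.landmark_names
    a, b, c = spec.half_axes
    pts = []
    for n in names:
        if n not in _LANDMARK_SITES:
            raise UnknownLandmarkError(
                f"unknown landmark {n!r}; candidates: {sorted(_LANDMARK_SITES)}"
            )
        u, w, anterior = _LANDMARK_SITES[n]
        v2 = 1.0 - u * u - w * w
        if v2 < 0:
            raise ParameterError(f"landmark site {n!r} has invalid parametric coordinates")
        v = np.sqrt(v2) * (1.0 if anterior else -1.0)
        pts.append([a * u, b * v, c * w])
    return LandmarkSet(list(names), np.array(pts), frame="model")


def _fracture_sites(spec: PhantomSpec, min_spacing_mm: float) -> list[FracturePoint]:
    """All candidate fracture sites: points every ``min_spacing_mm`` of arc."""
    sites: list[FracturePoint] = []
    for i in range(spec.n_rib_pairs):
        for side in ("left", "right"):
            line = spec.rib_centerline(i, side)
            seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            # Site positions centred within the rib, away from the free ends.
            n_sites = int(arc[-1] // min_spacing_mm)
            if n_sites < 1:
                continue
            offsets = arc[-1] / 2.0 + (np.arange(n_sites) - (n_sites - 1) / 2.0) * min_spacing_mm
            for s in offsets:
                p = np.array([np.interp(s, arc, line[:, k]) for k in range(3)])
                sites.append(FracturePoint(name="", point=p, rib_index=i, side=side))
    return sites


def place_fractures(
    spec: PhantomSpec, n: int, seed: int, min_spacing_mm: float = 20.0
) -> list[FracturePoint]:
    """Sample ``n`` fracture sites on rib centerlines, deterministic in ``seed``.

    Sites live on a fixed arc-length grid (spacing ``min_spacing_mm``)
    along each rib; a seeded permutation picks ``n`` of them, so growing
    ``n`` extends the selection without reshuffling earlier picks.
    """
    if n < 1:
        raise ParameterError("need n >= 1 fracture sites")
    if spec.n_rib_pairs < 1:
        raise ParameterError("phantom has no ribs to fracture")
    sites = _fracture_sites(spec, min_spacing_mm)
    if n > len(sites):
        raise CapacityError(
            f"requested {n} fractures but only {len(sites)} distinct rib sites exist "
            f"at {min_spacing_mm} mm spacing"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    chosen = [sites[j] for j in order[:n]]
    return [
        FracturePoint(
            name=f"fracture_{k:02d}", point=s.point, rib_index=s.rib_index, side=s.side
        )
        for k, s in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# Pose change
# ---------------------------------------------------------------------------

def _bend_displacement(points: np.ndarray, amplitude: float, z_center: float, z_half: float) -> np.ndarray:
    """Smooth low-frequency displacement field: sinusoidal x-bend + linear y-shear."""
    d = np.zeros_like(points)
    if amplitude == 0.0:
        return d
    if z_half <= 0:
        zh = np.zeros(points.shape[0])
    else:
        zh = (points[:, 2] - z_center) / z_half
    d[:, 0] = amplitude * np.sin(0.5 * np.pi * zh)
    d[:, 1] = 0.5 * amplitude * zh
    return d


def simulate_pose_change(
    points,
    deform: DeformationSpec,
    z_extent: tuple[float, float] | None = None,
):
    """Apply the scan-to-OR pose change to points.

    Order of operations: (1) smooth nonrigid bend, (2) ground-truth
    rigid transform, (3) i.i.d. isotropic Gaussian noise of sd
    ``landmark_noise_sd`` per point.  Returns ``(moved, rigid)`` where
    ``rigid`` is the exact rigid component for oracle use.  ``moved``
    matches the input kind (LandmarkSet in the patient frame, or array).

    ``z_extent`` fixes the (min, max) z range normalising the bend; by
    default the input points' own z range is used.
    """
    is_set = isinstance(points, LandmarkSet)
    pts = points.points if is_set else np.atleast_2d(np.asarray(points, dtype=float))
    if z_extent is None:
        zmin, zmax = float(pts[:, 2].min()), float(pts[:, 2].max())
    else:
        zmin, zmax = map(float, z_extent)
    z_center = 0.5 * (zmin + zmax)
    z_half = 0.5 * (zmax - zmin)

    moved = pts + _bend_displacement(pts, deform.bend_amplitude, z_center, z_half)
    rigid = deform.rigid()
    moved = rigid.apply(moved)
    if deform.landmark_noise_sd > 0:
        rng = np.random.default_rng(deform.seed)
        moved = moved + rng.normal(0.0, deform.landmark_noise_sd, size=moved.shape)
    if is_set:
        return points.with_points(moved, frame="patient"), rigid
    return moved, rigid
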