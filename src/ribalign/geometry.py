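"""Low-level triangle-mesh geometry: ray casting, surface projection, direction sets.

Everything here is pure NumPy, deterministic, and vectorised with
explicit chunking so memory stays bounded on large meshes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["fibonacci_sphere", "MeshRays", "MeshProximity", "closest_point_on_triangles"]

_EPS = 1e-12
# Pairwise (ray x triangle) work per chunk; bounds peak memory.
_CHUNK_PAIRS = 2.0e7


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` deterministic, near-uniform unit directions on the sphere."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden-angle increment
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class MeshRays:
    """Möller–Trumbore ray/triangle intersection against a fixed mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        self.v0 = vertices[faces[:, 0]]
        self.e1 = vertices[faces[:, 1]] - self.v0
        self.e2 = vertices[faces[:, 2]] - self.v0
        self.n_faces = len(faces)

    def _hit_ts(self, origins: np.ndarray, direction: np.ndarray, t_min: float) -> np.ndarray:
        """For each origin, smallest hit parameter ``t > t_min`` along one shared direction.

        Returns +inf where the ray escapes.  Chunked over origins.
        """
        origins = np.atleast_2d(origins)
        d = np.asarray(direction, dtype=float)
        # Per-triangle quantities shared by every origin.
        pvec = np.cross(d, self.e2)  # (M, 3)
        det = np.einsum("ij,ij->i", self.e1, pvec)  # (M,)
        ok = np.abs(det) > _EPS
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

        n = len(origins)
        out = np.full(n, np.inf)
        step = max(1, int(_CHUNK_PAIRS / max(self.n_faces, 1)))
        for s in range(0, n, step):
            o = origins[s : s + step]
            tvec = o[:, None, :] - self.v0[None, :, :]  # (r, M, 3)
            u = np.einsum("rmi,mi->rm", tvec, pvec) * inv_det
            qvec = np.cross(tvec, self.e1[None, :, :])
            v = np.einsum("rmi,i->rm", qvec, d) * inv_det
            t = np.einsum("rmi,mi->rm", qvec, self.e2) * inv_det
            hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > t_min)
            t = np.where(hit, t, np.inf)
            out[s : s + step] = t.min(axis=1)
        return out

    def hits_any(self, origins: np.ndarray, direction: np.ndarray, t_min: float = 0.0) -> np.ndarray:
        """Boolean per origin: does the ray along ``direction`` hit the mesh?"""
        return np.isfinite(self._hit_ts(origins, direction, t_min))

    def first_hit(self, origin: np.ndarray, direction: np.ndarray, t_min: float = 0.0):
        """(t, point) of the first intersection from one origin, or (inf, None)."""
        t = float(self._hit_ts(np.atleast_2d(origin), np.asarray(direction, float), t_min)[0])
        if not np.isfinite(t):
            return np.inf, None
        return t, np.asarray(origin, float) + t * np.asarray(direction, float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Even-odd containment test for a closed mesh (crossing parity).

        Uses a fixed irrational-slope direction to avoid edge grazing.
        """
        d = np.array([0.577215664901, 0.301029995664, 0.757575757575])
        d /= np.linalg.norm(d)
        points = np.atleast_2d(points)
        pvec = np.cross(d, self.e2)
        det = np.einsum("ij,ij->i", self.e1, pvec)
        ok = np.abs(det) > _EPS
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        n = len(points)
        crossings = np.zeros(n, dtype=np.int64)
        step = max(1, int(_CHUNK_PAIRS / max(self.n_faces, 1)))
        for s in range(0, n, step):
            o = points[s : s + step]
            tvec = o[:, None, :] - self.v0[None, :, :]
            u = np.einsum("rmi,mi->rm", tvec, pvec) * inv_det
            qvec = np.cross(tvec, self.e1[None, :, :])
            v = np.einsum("rmi,i->rm", qvec, d) * inv_det
            t = np.einsum("rmi,mi->rm", qvec, self.e2) * inv_det
            hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
            crossings[s : s + step] = hit.sum(axis=1)
        return crossings % 2 == 1


def closest_point_on_triangles(points: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on each triangle ``(a_i, b_i, c_i)`` to each ``points_i``.

    All arrays are (Q, 3); returns (closest (Q, 3), squared distance (Q,)).
    Plane projection clamped against the three edges.
    """
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    ap = points - a

    # Barycentric coordinates of the in-plane projection.
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    safe = np.abs(denom) > _EPS
    denom_s = np.where(safe, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / denom_s
    w = (d00 * d21 - d01 * d20) / denom_s
    inside = safe & (v >= 0) & (w >= 0) & (v + w <= 1) & (nn > _EPS)
    proj = a + v[:, None] * ab + w[:, None] * ac

    def _seg(p, s0, s1):
        sv = s1 - s0
        tt = np.einsum("ij,ij->i", p - s0, sv) / np.maximum(np.einsum("ij,ij->i", sv, sv), _EPS)
        tt = np.clip(tt, 0.0, 1.0)
        return s0 + tt[:, None] * sv

    best = _seg(points, a, b)
    best_d = np.einsum("ij,ij->i", points - best, points - best)
    for s0, s1 in ((b, c), (c, a)):
        cand = _seg(points, s0, s1)
        d = np.einsum("ij,ij->i", points - cand, points - cand)
        better = d < best_d
        best = np.where(better[:, None], cand, best)
        best_d = np.where(better, d, best_d)

    proj_d = np.einsum("ij,ij->i", points - proj, points - proj)
    use_proj = inside & (proj_d <= best_d)
    closest = np.where(use_proj[:, None], proj, best)
    dist2 = np.where(use_proj, proj_d, best_d)
    return closest, dist2


class MeshProximity:
    """Nearest-point-on-surface queries against a fixed triangle mesh.

    Candidate faces come from a k-d tree over face centroids plus the
    faces incident to the nearest vertex; the exact point-triangle
    distance then selects the winner.  Exact provided the true nearest
    face is within the ``k`` nearest centroids or touches the nearest
    vertex — ample for the CT-scale meshes used here.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 32):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.k = min(k, len(self.faces))
        centroids = self.vertices[self.faces].mean(axis=1)
        self._face_tree = cKDTree(centroids)
        self._vert_tree = cKDTree(self.vertices)
        self._vert_faces: list[list[int]] = [[] for _ in range(len(self.vertices))]
        for fi, f in enumerate(self.faces):
            for vi in f:
                self._vert_faces[vi].append(fi)

    def project(self, points: np.ndarray):
        """Return (surface points (Q,3), distances (Q,), face indices (Q,))."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._face_tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        _, nv = self._vert_tree.query(points)
        out_pts = np.empty_like(points)
        out_d = np.empty(len(points))
        out_f = np.empty(len(points), dtype=np.int64)
        for i, p in enumerate(points):
            fids = np.unique(np.concatenate([cand[i], np.asarray(self._vert_faces[int(nv[i])], dtype=np.int64)]))
            tri = self.vertices[self.faces[fids]]
            pts = np.broadcast_to(p, (len(fids), 3))
            closest, d2 = closest_point_on_triangles(pts, tri[:, 0], tri[:, 1], tri[:, 2])
            j = int(np.argmin(d2))
            out_pts[i] = closest[j]
            out_d[i] = np.sqrt(d2[j])
            out_f[i] = fids[j]
        return out_pts, out_d, out_f
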