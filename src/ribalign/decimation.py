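"""Quadric-error edge-collapse surface simplification.

Classic Garland–Heckbert decimation: each vertex carries the sum of the
squared-plane-distance quadrics of its incident faces; edges are
collapsed cheapest-first into the position minimising the combined
quadric, until the face budget is met.  Collapses that would flip a
surviving face's normal are skipped, which preserves local orientation
and (for clean inputs) watertightness.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["quadric_decimate"]


def _face_quadric(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-15:
        return np.zeros((4, 4))
    n = n / norm
    d = -np.dot(n, p0)
    plane = np.array([n[0], n[1], n[2], d])
    return np.outer(plane, plane)


def _optimal_position(Q: np.ndarray, fallback: np.ndarray) -> tuple[np.ndarray, float]:
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        # Guard against near-singular quadrics (flat/linear neighbourhoods).
        if np.linalg.cond(A) < 1e7:
            x = np.linalg.solve(A, b)
        else:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        x = None
    candidates = [fallback[0], fallback[1], 0.5 * (fallback[0] + fallback[1])]
    if x is not None:
        candidates.insert(0, x)
    best, best_cost = None, np.inf
    for c in candidates:
        h = np.append(c, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = c, cost
    return best, max(best_cost, 0.0)


def quadric_decimate(
    vertices: np.ndarray, faces: np.ndarray, target_faces: int
) -> tuple[np.ndarray, np.ndarray]:
    """Decimate a triangle mesh to at most ``target_faces`` faces.

    Returns new (vertices, faces) arrays; unreferenced vertices are
    dropped.  The mesh should be manifold; non-collapsible edges are
    skipped rather than forced.
    """
    V = np.asarray(vertices, dtype=float).copy()
    F = [list(map(int, f)) for f in faces]
    alive_face = np.ones(len(F), dtype=bool)
    n_alive = len(F)

    quadrics = np.zeros((len(V), 4, 4))
    vert_faces: list[set[int]] = [set() for _ in range(len(V))]
    for fi, (i, j, k) in enumerate(F):
        Kq = _face_quadric(V[i], V[j], V[k])
        for vi in (i, j, k):
            quadrics[vi] += Kq
            vert_faces[vi].add(fi)

    version = np.zeros(len(V), dtype=np.int64)
    counter = iter(range(1 << 62))  # tiebreak so heap never compares arrays

    def edge_entry(u: int, v: int):
        Q = quadrics[u] + quadrics[v]
        pos, cost = _optimal_position(Q, (V[u], V[v]))
        return (cost, next(counter), u, v, int(version[u]), int(version[v]), pos)

    edges = set()
    for i, j, k in F:
        for a, b in ((i, j), (j, k), (k, i)):
            edges.add((min(a, b), max(a, b)))
    heap = [edge_entry(u, v) for u, v in edges]
    heapq.heapify(heap)

    def collapse_ok(u: int, v: int, pos: np.ndarray) -> bool:
        # Reject collapses that flip the normal of any surviving face.
        for fi in vert_faces[u] | vert_faces[v]:
            if not alive_face[fi]:
                continue
            tri = F[fi]
            if u in tri and v in tri:
                continue  # face dies in the collapse
            pts_old = [V[x] for x in tri]
            pts_new = [pos if x in (u, v) else V[x] for x in tri]
            n_old = np.cross(pts_old[1] - pts_old[0], pts_old[2] - pts_old[0])
            n_new = np.cross(pts_new[1] - pts_new[0], pts_new[2] - pts_new[0])
            if np.dot(n_old, n_new) <= 1e-12:
                return False
        return True

    while n_alive > target_faces and heap:
        cost, _, u, v, ver_u, ver_v, pos = heapq.heappop(heap)
        if version[u] != ver_u or version[v] != ver_v:
            continue  # stale entry
        if not (vert_faces[u] and vert_faces[v]):
            continue
        if not collapse_ok(u, v, pos):
            continue

        # Contract v into u at the optimal position.
        V[u] = pos
        quadrics[u] = quadrics[u] + quadrics[v]
        dying = [fi for fi in vert_faces[u] & vert_faces[v] if alive_face[fi]]
        for fi in dying:
            alive_face[fi] = False
            n_alive -= 1
            for x in F[fi]:
                vert_faces[x].discard(fi)
        for fi in list(vert_faces[v]):
            if not alive_face[fi]:
                vert_faces[v].discard(fi)
                continue
            F[fi] = [u if x == v else x for x in F[fi]]
            vert_faces[u].add(fi)
        vert_faces[v] = set()
        version[u] += 1
        version[v] += 1

        # Refresh heap entries around u.
        neighbours = set()
        for fi in vert_faces[u]:
            if alive_face[fi]:
                neighbours.update(F[fi])
        neighbours.discard(u)
        for w in neighbours:
            a, b = (u, w) if u < w else (w, u)
            heapq.heappush(heap, edge_entry(a, b))

    new_faces = np.array([F[fi] for fi in range(len(F)) if alive_face[fi]], dtype=np.int64)
    used = np.unique(new_faces)
    remap = np.full(len(V), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return V[used], remap[new_faces]
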