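"""Quadric edge-collapse mesh decimation.

Garland–Heckbert style simplification: every vertex accumulates the quadric
of its incident face planes; an edge collapse is scored by the quadric error
of the merged vertex at its optimal position.  Collapses are applied
greedily from a lazy heap until the face budget is met or the cheapest
remaining collapse would exceed the error guard.

A collapse is rejected when it would flip the orientation of a surviving
face, which keeps the surface from folding over itself.  Duplicate faces
that can appear along collapsed seams are left for the dedupe cleanup step
that follows decimation in the pipeline.

Provenance is tracked per face: each output face carries the set of input
face ids it absorbed, and the union over all output faces covers the input
surface.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["quadric_decimate"]


def _bulk_entries(edge_arr: np.ndarray, vq: np.ndarray, vertices: np.ndarray, tick):
    """Vectorized initial heap entries for all edges at once."""
    q = vq[edge_arr[:, 0]] + vq[edge_arr[:, 1]]
    a = q[:, :3, :3]
    b = -q[:, :3, 3]
    det = np.linalg.det(a)
    scale = (np.einsum("ijj->i", a) / 3.0) ** 3
    solvable = np.abs(det) > 1e-9 * np.abs(scale)
    p1 = vertices[edge_arr[:, 0]]
    p2 = vertices[edge_arr[:, 1]]
    opt = 0.5 * (p1 + p2)
    if solvable.any():
        opt = opt.copy()
        opt[solvable] = np.linalg.solve(a[solvable], b[solvable][..., None])[..., 0]
    cands = np.stack([opt, p1, 0.5 * (p1 + p2), p2], axis=1)  # (m, 4, 3)
    h = np.concatenate([cands, np.ones((*cands.shape[:2], 1))], axis=2)  # (m, 4, 4)
    errs = np.einsum("mci,mij,mcj->mc", h, q, h)
    errs[~solvable, 0] = np.inf
    best = np.argmin(errs, axis=1)
    rows = np.arange(len(edge_arr))
    best_err = np.maximum(errs[rows, best], 0.0)
    best_pos = cands[rows, best]
    return [
        (float(best_err[i]), next(tick), int(edge_arr[i, 0]), int(edge_arr[i, 1]), 0, 0, best_pos[i])
        for i in rows
    ]


def _face_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Fundamental error quadric K = p p^T of each face plane (n, 4, 4)."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    d = -np.einsum("ij,ij->i", n, v0)
    p = np.concatenate([n, d[:, None]], axis=1)  # (n, 4)
    return p[:, :, None] * p[:, None, :]


def _optimal_position(q: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, float]:
    """Placement minimizing v^T Q v; falls back to best of {p1, mid, p2}."""
    a = q[:3, :3]
    b = -q[:3, 3]
    pos = None
    # determinant gate: only invert comfortably non-singular quadrics
    scale = (np.trace(a) / 3.0) ** 3
    if abs(np.linalg.det(a)) > 1e-9 * abs(scale) and scale != 0:
        pos = np.linalg.solve(a, b)
    candidates = [pos] if pos is not None else []
    candidates += [p1, 0.5 * (p1 + p2), p2]
    best, best_err = None, np.inf
    for c in candidates:
        h = np.append(c, 1.0)
        err = float(h @ q @ h)
        if err < best_err:
            best, best_err = c, err
    return best, max(best_err, 0.0)


def quadric_decimate(
    vertices: np.ndarray,
    faces: np.ndarray,
    target_faces: int,
    max_error: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[set]]:
    """Decimate (vertices, faces) to at most ``target_faces`` live faces.

    Parameters
    ----------
    max_error : optional guard; collapses whose quadric error exceeds
        ``max_error**2`` are never applied (error is a squared-distance
        scale), so geometric detail above that scale is preserved even if
        the face budget is not reached.

    Returns
    -------
    (new_vertices, new_faces, provenance) where ``provenance[i]`` is the set
    of input face ids represented by output face ``i``.
    """
    vertices = np.asarray(vertices, dtype=np.float64).copy()
    faces = np.asarray(faces, dtype=np.int64).copy()
    n_faces = len(faces)
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    err_cap = np.inf if max_error is None else float(max_error) ** 2

    quadrics = _face_quadrics(vertices, faces)
    vq = np.zeros((len(vertices), 4, 4))
    np.add.at(vq, faces[:, 0], quadrics)
    np.add.at(vq, faces[:, 1], quadrics)
    np.add.at(vq, faces[:, 2], quadrics)

    face_alive = np.ones(n_faces, dtype=bool)
    provenance: list[set] = [{i} for i in range(n_faces)]
    vert_faces: list[set] = [set() for _ in range(len(vertices))]
    for fi, f in enumerate(faces):
        for v in f:
            vert_faces[v].add(fi)

    version = np.zeros(len(vertices), dtype=np.int64)
    tick = iter(range(10**18))  # heap tie-break so arrays are never compared

    def edge_entry(v1: int, v2: int):
        q = vq[v1] + vq[v2]
        pos, err = _optimal_position(q, vertices[v1], vertices[v2])
        return (err, next(tick), v1, v2, version[v1], version[v2], pos)

    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    edge_arr = np.unique(e, axis=0)
    heap = _bulk_entries(edge_arr, vq, vertices, tick)
    heapq.heapify(heap)

    alive_count = n_faces
    while alive_count > target_faces and heap:
        err, _, v1, v2, ver1, ver2, pos = heapq.heappop(heap)
        if version[v1] != ver1 or version[v2] != ver2:
            continue  # stale entry
        if err > err_cap:
            break
        f1, f2 = vert_faces[v1], vert_faces[v2]
        shared = {fi for fi in (f1 & f2) if face_alive[fi]}
        if not shared:
            continue  # no longer an edge of the live mesh

        # orientation guard: surviving incident faces must not flip
        affected = [fi for fi in (f1 | f2) if face_alive[fi] and fi not in shared]
        flip = False
        for fi in affected:
            f = faces[fi]
            old = np.cross(vertices[f[1]] - vertices[f[0]], vertices[f[2]] - vertices[f[0]])
            newv = [pos if v in (v1, v2) else vertices[v] for v in f]
            new = np.cross(newv[1] - newv[0], newv[2] - newv[0])
            if old @ new <= 0:
                flip = True
                break
        if flip:
            continue

        # apply collapse: v2 merges into v1 at pos
        vertices[v1] = pos
        vq[v1] = vq[v1] + vq[v2]
        orphaned: set = set()
        for fi in shared:
            face_alive[fi] = False
            alive_count -= 1
            orphaned |= provenance[fi]
            for v in faces[fi]:
                vert_faces[v].discard(fi)
        for fi in list(f2):
            if face_alive[fi]:
                faces[fi][faces[fi] == v2] = v1
                vert_faces[v1].add(fi)
            vert_faces[v2].discard(fi)
        # orphaned input faces stay covered by a surviving neighbor
        survivors = sorted(fi for fi in vert_faces[v1] if face_alive[fi])
        if survivors:
            provenance[survivors[0]] |= orphaned
        version[v1] += 1
        version[v2] += 1

        neighbors = set()
        for fi in vert_faces[v1]:
            if face_alive[fi]:
                neighbors.update(int(v) for v in faces[fi])
        neighbors.discard(v1)
        for nb in neighbors:
            heapq.heappush(heap, edge_entry(min(v1, nb), max(v1, nb)))

    live = np.where(face_alive)[0]
    out_faces = faces[live]
    used = np.unique(out_faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[out_faces], [provenance[fi] for fi in live]
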