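"""Triangulated surface model of the viable myocardium.

The binary viable-myocardium mask is turned into a closed triangle mesh by
marching cubes (vertices in physical mm), then prepared for skeletonization:
decimated to a face budget with an error guard, stripped of duplicate faces
left by meshing seams, cleared of isolated specks below a triangle-count
threshold (noise), and finally normalized into a centered unit cube for the
contraction solver.  All geometric thresholds downstream of the solver are
evaluated in mm, so the unit-cube transform is always inverted before any
metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .decimation import quadric_decimate
from .volume import BinaryMask

__all__ = [
    "SurfaceMesh",
    "UnitCubeTransform",
    "mask_to_mesh",
    "decimate",
    "remove_duplicate_faces",
    "filter_small_components",
    "normalize_to_unit_cube",
    "clean_mesh",
    "write_mesh",
    "read_mesh",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm coordinates.

    ``provenance`` optionally maps each face back to the set of source-face
    ids of the mesh it was decimated from.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: list[set] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def face_components(self) -> list[np.ndarray]:
        """Face-connected components (shared-edge adjacency), list of face-id arrays."""
        if not len(self.faces):
            return []
        labels = trimesh.graph.connected_component_labels(
            self.to_trimesh().face_adjacency, node_count=len(self.faces)
        )
        return [np.where(labels == c)[0] for c in np.unique(labels)]

    def vertex_adjacency(self) -> set[tuple[int, int]]:
        """Undirected vertex-pair edges of the triangulation."""
        e = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        return {tuple(row) for row in np.unique(e, axis=0)}


@dataclass(frozen=True)
class UnitCubeTransform:
    """Uniform scale + translation mapping mm space into [-0.5, 0.5]^3."""

    scale: float
    translation: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) + np.asarray(self.translation)) * self.scale

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) / self.scale - np.asarray(self.translation)


def mask_to_mesh(mask: BinaryMask) -> SurfaceMesh:
    """Closed isosurface of a binary mask at level 0.5, vertices in mm.

    The grid is padded with background so the surface always closes at the
    volume boundary; vertex coordinates account for the pad and apply the
    mask's spacing and origin.
    """
    if not mask.grid.any():
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.grid, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
    return SurfaceMesh(verts, faces)


def decimate(
    mesh: SurfaceMesh,
    target_faces: int = 10_000,
    max_error_mm: float | None = 0.5,
) -> SurfaceMesh:
    """Reduce the face count by quadric edge collapse.

    Stops at ``target_faces`` or earlier if the cheapest remaining collapse
    would displace the surface by more than ``max_error_mm`` (default 0.5 mm,
    half a typical voxel; pass None to disable).  The guard takes precedence
    over the face budget: geometric detail above that scale is preserved, so
    structurally complex regions keep more faces than smooth ones — the
    signal the heterogeneity index measures.  A mesh already within budget
    is returned unchanged with identity provenance.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    if mesh.n_faces <= target_faces:
        return SurfaceMesh(
            mesh.vertices.copy(), mesh.faces.copy(), [{i} for i in range(mesh.n_faces)]
        )
    verts, faces, prov = quadric_decimate(mesh.vertices, mesh.faces, target_faces, max_error_mm)
    return SurfaceMesh(verts, faces, prov)


def remove_duplicate_faces(mesh: SurfaceMesh) -> SurfaceMesh:
    """Drop faces sharing the same vertex set, orientation-insensitively.

    The first occurrence (lowest face id) of each vertex multiset is kept;
    degenerate faces (a repeated vertex) are dropped too.  Vertices are
    untouched.
    """
    if not mesh.n_faces:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    key = np.sort(mesh.faces, axis=1)
    nondegenerate = (key[:, 0] != key[:, 1]) & (key[:, 1] != key[:, 2])
    _, first = np.unique(key, axis=0, return_index=True)
    keep = np.zeros(mesh.n_faces, dtype=bool)
    keep[first] = True
    keep &= nondegenerate
    prov = [mesh.provenance[i] for i in np.where(keep)[0]] if mesh.provenance else None
    return SurfaceMesh(mesh.vertices.copy(), mesh.faces[keep], prov)


def filter_small_components(mesh: SurfaceMesh, min_triangles: int = 100) -> SurfaceMesh:
    """Remove isolated face-connected components with fewer than
    ``min_triangles`` triangles (default 100) — typically meshing noise.

    Connectivity is face adjacency via shared edges.  Removing everything is
    allowed (downstream stages then report zero channels).
    """
    if min_triangles < 0:
        raise ValueError("min_triangles must be >= 0")
    keep_faces: list[np.ndarray] = [
        comp for comp in mesh.face_components() if len(comp) >= min_triangles
    ]
    if not keep_faces:
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    idx = np.sort(np.concatenate(keep_faces))
    faces = mesh.faces[idx]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    prov = [mesh.provenance[i] for i in idx] if mesh.provenance else None
    return SurfaceMesh(mesh.vertices[used], remap[faces], prov)


def normalize_to_unit_cube(mesh: SurfaceMesh) -> tuple[SurfaceMesh, UnitCubeTransform]:
    """Center the mesh in a unit cube, longest axis spanning exactly 1.

    Uniform scaling (aspect preserved).  Returns the transform whose
    ``invert`` maps unit-cube coordinates back to mm.
    """
    if not mesh.n_vertices:
        raise ValueError("cannot normalize an empty mesh")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    extent = float((hi - lo).max())
    if extent <= 0:
        raise ValueError("mesh has zero spatial extent")
    center = (lo + hi) / 2.0
    tf = UnitCubeTransform(scale=1.0 / extent, translation=tuple(-center))
    out = SurfaceMesh(tf.apply(mesh.vertices), mesh.faces.copy(), mesh.provenance)
    return out, tf


def clean_mesh(
    mesh: SurfaceMesh,
    target_faces: int = 10_000,
    max_error_mm: float | None = 0.5,
    min_triangles: int = 100,
) -> SurfaceMesh:
    """Pipeline cleanup: decimate, dedupe, drop sub-threshold specks."""
    out = decimate(mesh, target_faces, max_error_mm)
    out = remove_duplicate_faces(out)
    return filter_small_components(out, min_triangles)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Export to PLY/STL (format chosen by extension)."""
    mesh.to_trimesh().export(str(path))


def read_mesh(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
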