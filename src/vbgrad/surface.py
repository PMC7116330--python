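"""Triangulated surface meshes: one-ring adjacency, masks, GIFTI I/O.

A cortical surface is a closed triangle mesh whose vertices carry the
per-node features (fMRI time series, tractogram profiles, ...).  The
searchlight neighbourhood of a vertex is its *one-ring*: every vertex
sharing a triangle with it, which on cortical-quality meshes means 5 or
6 neighbours.

Icospheres (recursively subdivided icosahedra projected to the unit
sphere) serve as synthetic stand-ins for cortical surfaces: they are
closed, nearly uniform, and have the same 5-or-6-neighbour one-ring
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import AlignmentError, MeshError, ParameterError

__all__ = [
    "SurfaceMesh",
    "VertexMask",
    "ClusterLabels",
    "one_ring",
    "k_ring",
    "make_icosphere",
    "read_surface",
    "write_surface",
    "read_scalars",
    "write_scalars",
    "read_labels",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """Vertex coordinates (n x 3, mm) and triangle index list (m x 3, 0-based)."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be n x 3, got {v.shape}")
        if t.ndim != 2 or t.shape[1] != 3:
            raise MeshError(f"triangles must be m x 3, got {t.shape}")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise MeshError(
                f"triangle index out of range [0, {len(v)}): "
                f"min {t.min()}, max {t.max()}"
            )
        if t.size and np.any(
            (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        ):
            raise MeshError("degenerate triangle (repeated vertex index)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def orphan_vertices(self) -> np.ndarray:
        """Vertices referenced by no triangle (excluded as searchlight centers)."""
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.triangles.ravel()] = True
        return np.flatnonzero(~used)


@dataclass(frozen=True)
class VertexMask:
    """Binary inclusion mask over vertices (e.g. medial-wall exclusion)."""

    included: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.included).astype(bool)
        if m.ndim != 1:
            raise MeshError("mask must be a vector")
        if m.sum() < 3:
            raise MeshError(f"mask keeps only {int(m.sum())} vertices; need >= 3")
        object.__setattr__(self, "included", m)

    @property
    def n(self) -> int:
        return self.included.shape[0]


@dataclass(frozen=True)
class ClusterLabels:
    """Per-vertex non-negative integer labels; 0 means unassigned/masked out."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 1:
            raise MeshError("labels must be a vector")
        if lab.size and lab.min() < 0:
            raise MeshError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def one_ring(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Per-vertex adjacency: j is a neighbour of i iff they share a triangle.

    Lists are sorted ascending and contain no self-entries; adjacency is
    symmetric by construction.
    """
    nbrs: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return [np.array(sorted(s), dtype=int) for s in nbrs]


def k_ring(mesh: SurfaceMesh, k: int) -> list[np.ndarray]:
    """Breadth-first k-ring neighbourhoods (k >= 1; k=1 is the one-ring).

    Non-canonical extension: searchlight analyses in this package default
    to the strict one-ring ("directly adjacent" vertices).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    ring1 = one_ring(mesh)
    if k == 1:
        return ring1
    out = []
    for v in range(mesh.n_vertices):
        seen = {v}
        frontier = set(ring1[v].tolist())
        seen |= frontier
        for _ in range(k - 1):
            nxt = set()
            for u in frontier:
                nxt.update(ring1[u].tolist())
            frontier = nxt - seen
            seen |= frontier
        seen.discard(v)
        out.append(np.array(sorted(seen), dtype=int))
    return out


def make_icosphere(subdivisions: int) -> SurfaceMesh:
    """Icosahedron subdivided ``s`` times, projected to the unit sphere.

    Vertex count is ``10 * 4**s + 2`` (12, 42, 162, 642, ...).
    """
    if not 0 <= int(subdivisions) <= 6:
        raise ParameterError(f"subdivisions must be in [0, 6], got {subdivisions}")
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=1.0)
    return SurfaceMesh(np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=int))


# ---------------------------------------------------------------------------
# GIFTI I/O (nibabel).  CSV fallbacks are provided for every reader/writer.
# ---------------------------------------------------------------------------


def _is_csv(path) -> bool:
    return str(path).lower().endswith((".csv", ".txt"))


def read_surface(path) -> SurfaceMesh:
    """Read mesh geometry from a GIFTI ``.surf.gii`` file.

    CSV fallback: a pair ``<stem>.vertices.csv`` / ``<stem>.triangles.csv``
    read by passing either member of the pair.
    """
    p = str(path)
    if _is_csv(p):
        stem = p.rsplit(".", 2)[0]
        v = np.loadtxt(stem + ".vertices.csv", delimiter=",", ndmin=2)
        t = np.loadtxt(stem + ".triangles.csv", delimiter=",", ndmin=2).astype(int)
        return SurfaceMesh(v, t)
    import nibabel as nib

    img = nib.load(p)
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
    if not coords or not tris:
        raise MeshError(f"{p}: no pointset/triangle arrays; not a surface GIFTI")
    return SurfaceMesh(coords[0].data.astype(float), tris[0].data.astype(int))


def write_surface(path, mesh: SurfaceMesh) -> None:
    p = str(path)
    if _is_csv(p):
        stem = p.rsplit(".", 2)[0]
        np.savetxt(stem + ".vertices.csv", mesh.vertices, delimiter=",")
        np.savetxt(stem + ".triangles.csv", mesh.triangles, fmt="%d", delimiter=",")
        return
    import nibabel as nib

    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.triangles.astype(np.int32),
                intent="NIFTI_INTENT_TRIANGLE",
                datatype="NIFTI_TYPE_INT32",
            ),
        ]
    )
    nib.save(img, p)


def read_scalars(path, expect_n: Optional[int] = None) -> np.ndarray:
    """Read per-vertex data from a functional/shape GIFTI (or CSV).

    A multi-map file stacks into an ``n x T`` array (one column per
    map).  A single map returns shape ``(n,)``.  If ``expect_n`` is
    given, a mismatching vertex count raises :class:`AlignmentError`
    reporting both counts.
    """
    p = str(path)
    if _is_csv(p):
        data = np.loadtxt(p, delimiter=",", ndmin=2)
    else:
        import nibabel as nib

        img = nib.load(p)
        if not img.darrays:
            raise AlignmentError(f"{p}: GIFTI file contains no data arrays")
        cols = [np.asarray(d.data, dtype=float).ravel() for d in img.darrays]
        lens = {len(c) for c in cols}
        if len(lens) != 1:
            raise AlignmentError(f"{p}: maps have inconsistent lengths {sorted(lens)}")
        data = np.column_stack(cols)
    if expect_n is not None and data.shape[0] != expect_n:
        raise AlignmentError(
            f"{p}: data has {data.shape[0]} vertices but surface has {expect_n}"
        )
    return data[:, 0] if data.shape[1] == 1 else data


def write_scalars(path, data: np.ndarray) -> None:
    """Write per-vertex data (n or n x T) as functional GIFTI or CSV."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    p = str(path)
    if _is_csv(p):
        np.savetxt(p, arr, delimiter=",")
        return
    import nibabel as nib

    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                arr[:, j].astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
            for j in range(arr.shape[1])
        ]
    )
    nib.save(img, p)


def read_labels(path, expect_n: Optional[int] = None) -> ClusterLabels:
    """Read integer cluster labels from a label GIFTI or CSV."""
    data = read_scalars(path, expect_n=expect_n)
    if data.ndim != 1:
        raise AlignmentError("label file must contain exactly one map")
    return ClusterLabels(np.round(data).astype(int))
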