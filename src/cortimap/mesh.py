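"""Triangle-mesh geometry for surface-based statistics.

The cortical surface is represented as a triangulated mesh. All spatial
quantities used downstream — vertex-wise areas, neighbourhood smoothing,
connected clusters — are defined on this mesh through edge adjacency:
two vertices are neighbours iff they share a mesh edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc


@dataclass(frozen=True)
class SmoothSpec:
    """Iterative neighbour-averaging smoothing.

    Each step replaces every vertex value by the unweighted mean of the
    vertex and its edge neighbours.  ``fwhm_mm`` is informational only
    (the empirical kernel width depends on mesh edge length); the number
    of steps is what the algorithm consumes.
    """

    steps: int = 10
    fwhm_mm: float | None = None

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("smoothing steps must be >= 0")


class TriangleMesh:
    """Closed triangulated surface: vertex coordinates (mm) and faces.

    Faces are triples of 0-based vertex indices.  Adjacency, face areas,
    vertex-wise areas and the smoothing operator are computed lazily and
    cached.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("face indices out of range")
        self.vertices = vertices
        self.faces = faces
        self._cache: dict[str, object] = {}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def face_areas(self) -> np.ndarray:
        """Area (mm^2) of each triangular face."""
        if "face_areas" not in self._cache:
            v = self.vertices
            a, b, c = (v[self.faces[:, i]] for i in range(3))
            cross = np.cross(b - a, c - a)
            areas = 0.5 * np.linalg.norm(cross, axis=1)
            if np.any(areas <= 0):
                warnings.warn(
                    f"{int(np.sum(areas <= 0))} degenerate face(s) with zero "
                    "area contribute nothing to vertex areas",
                    stacklevel=2,
                )
            self._cache["face_areas"] = areas
        return self._cache["face_areas"]  # type: ignore[return-value]

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Vertex-wise area: one third of the summed areas of adjacent faces.

        Summed over any vertex set this reproduces the enclosed triangle
        area exactly, which makes regional areas additive.
        """
        if "vertex_areas" not in self._cache:
            fa = self.face_areas()
            va = np.zeros(self.n_vertices)
            for i in range(3):
                np.add.at(va, self.faces[:, i], fa / 3.0)
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]  # type: ignore[return-value]

    # ------------------------------------------------------------------
    # adjacency and smoothing
    # ------------------------------------------------------------------
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency over mesh edges (CSR)."""
        if "adjacency" not in self._cache:
            f = self.faces
            rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
            cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
            data = np.ones(len(rows), dtype=np.int8)
            n = self.n_vertices
            adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
            adj = adj + adj.T
            adj.data[:] = 1
            self._cache["adjacency"] = adj
        return self._cache["adjacency"]  # type: ignore[return-value]

    def neighbors(self, vertex: int) -> np.ndarray:
        """Edge neighbours of one vertex (sorted)."""
        adj = self.adjacency()
        return adj.indices[adj.indptr[vertex]:adj.indptr[vertex + 1]]

    def smoothing_operator(self) -> sp.csr_matrix:
        """One smoothing step as a sparse row-stochastic matrix.

        Row v averages {v} and its edge neighbours with equal weight.
        """
        if "smooth_op" not in self._cache:
            adj = self.adjacency().astype(float)
            n = self.n_vertices
            a = adj + sp.identity(n, format="csr")
            deg = np.asarray(a.sum(axis=1)).ravel()
            d_inv = sp.diags(1.0 / deg)
            self._cache["smooth_op"] = (d_inv @ a).tocsr()
        return self._cache["smooth_op"]  # type: ignore[return-value]

    def edge_lengths(self) -> sp.csr_matrix:
        """Sparse symmetric matrix of Euclidean edge lengths (mm)."""
        if "edge_lengths" not in self._cache:
            adj = self.adjacency().tocoo()
            d = np.linalg.norm(
                self.vertices[adj.row] - self.vertices[adj.col], axis=1
            )
            self._cache["edge_lengths"] = sp.csr_matrix(
                (d, (adj.row, adj.col)), shape=adj.shape
            )
        return self._cache["edge_lengths"]  # type: ignore[return-value]


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex area map (mm^2); see :meth:`TriangleMesh.vertex_areas`."""
    return mesh.vertex_areas()


def region_area(areas: np.ndarray, mask) -> float:
    """Summed vertex-wise area (mm^2) over a set of vertex indices."""
    idx = np.asarray(sorted(mask), dtype=np.int64)
    if idx.size == 0:
        return 0.0
    if idx.min() < 0 or idx.max() >= len(areas):
        raise IndexError("mask contains out-of-range vertex indices")
    return float(np.asarray(areas)[idx].sum())


def smooth(values: np.ndarray, mesh: TriangleMesh, spec: SmoothSpec) -> np.ndarray:
    """Apply ``spec.steps`` rounds of neighbour averaging to a per-vertex map.

    Accepts real or complex maps (complex maps are smoothed component-wise,
    which a single complex matrix-vector product already does) and 2-D
    arrays of shape (n_vertices, k) smoothed column-wise.
    """
    values = np.asarray(values)
    if values.shape[0] != mesh.n_vertices:
        raise ValueError("map length does not match mesh vertex count")
    if spec.steps == 0:
        return values.copy()
    op = mesh.smoothing_operator()
    out = values.astype(complex if np.iscomplexobj(values) else float)
    for _ in range(spec.steps):
        out = op @ out
    return out


def connected_components(mask, mesh: TriangleMesh) -> list[list[int]]:
    """Partition a vertex set into edge-connected components.

    Components are sorted by their smallest contained vertex index, and
    the vertices within each component are sorted ascending.
    """
    idx = np.asarray(sorted(set(mask)), dtype=np.int64)
    if idx.size == 0:
        return []
    sub = mesh.adjacency()[idx][:, idx]
    n_comp, labels = _cc(sub, directed=False)
    comps = [idx[labels == k].tolist() for k in range(n_comp)]
    comps.sort(key=lambda c: c[0])
    return comps
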