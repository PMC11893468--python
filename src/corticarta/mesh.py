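"""Triangulated cortical sheets and mesh geometry helpers.

A :class:`CorticalSheet` carries matched outer (pial) and inner (white-matter)
surfaces with shared triangulation, per-vertex spherical coordinates, and a
hemisphere label per vertex.  All downstream operations (equivolumetric
profiling, decimation, geodesic smoothing, spin permutation) work on this
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "CorticalSheet",
    "edge_graph",
    "vertex_areas",
    "mesh_edges",
    "farthest_point_sample",
    "is_connected_subset",
]


@dataclass
class CorticalSheet:
    """Matched outer/inner triangulated surfaces for two hemispheres.

    Parameters
    ----------
    outer_vertices, inner_vertices:
        ``(N, 3)`` float arrays in millimetres, vertex-matched.
    faces:
        ``(M, 3)`` integer array of vertex indices, shared by both surfaces.
    sphere_coordinates:
        ``(N, 3)`` unit-norm coordinates of each vertex on the hemisphere
        sphere (used for spin permutations).
    hemisphere:
        length-``N`` array of ``"L"`` / ``"R"`` labels.
    hemisphere_centers:
        mapping hemisphere label -> ``(3,)`` centre used when the sheet was
        laid out in space.
    """

    outer_vertices: np.ndarray
    inner_vertices: np.ndarray
    faces: np.ndarray
    sphere_coordinates: np.ndarray
    hemisphere: np.ndarray
    hemisphere_centers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outer_vertices = np.asarray(self.outer_vertices, dtype=float)
        self.inner_vertices = np.asarray(self.inner_vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.sphere_coordinates = np.asarray(self.sphere_coordinates, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        n = self.outer_vertices.shape[0]
        if self.inner_vertices.shape != self.outer_vertices.shape:
            raise ValueError("outer and inner surfaces must be vertex-matched")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("faces reference invalid vertex indices")
        thickness = self.thickness()
        if np.any(thickness <= 0):
            raise ValueError("per-vertex thickness must be strictly positive")
        norms = np.linalg.norm(self.sphere_coordinates, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sphere coordinates must have unit norm")

    @property
    def n_vertices(self) -> int:
        return self.outer_vertices.shape[0]

    def thickness(self) -> np.ndarray:
        """Per-vertex Euclidean distance between outer and inner surfaces."""
        return np.linalg.norm(self.outer_vertices - self.inner_vertices, axis=1)

    def hemisphere_mask(self, label: str) -> np.ndarray:
        return self.hemisphere == label

    def graph(self, surface: str = "outer") -> sparse.csr_matrix:
        """Sparse adjacency of the mesh with Euclidean edge lengths."""
        verts = self.outer_vertices if surface == "outer" else self.inner_vertices
        return edge_graph(verts, self.faces)


def mesh_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges ``(E, 2)`` of a triangulation."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def edge_graph(vertices: np.ndarray, faces: np.ndarray) -> sparse.csr_matrix:
    """Symmetric sparse graph of mesh edges weighted by Euclidean length."""
    edges = mesh_edges(faces)
    w = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    n = vertices.shape[0]
    g = sparse.coo_matrix(
        (np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    return g.tocsr()


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex surface area as one-third of incident triangle areas.

    Raises
    ------
    ValueError
        if any face is degenerate (zero area); the offending face index is
        reported.
    """
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    cross = np.cross(v1 - v0, v2 - v0)
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    bad = np.flatnonzero(tri_area <= 0)
    if bad.size:
        raise ValueError(f"degenerate face(s) with zero area: indices {bad[:5].tolist()}")
    areas = np.zeros(vertices.shape[0])
    for k in range(3):
        np.add.at(areas, faces[:, k], tri_area / 3.0)
    return areas


def farthest_point_sample(
    graph: sparse.csr_matrix,
    candidates: np.ndarray,
    k: int,
    start: int | None = None,
) -> np.ndarray:
    """Greedy farthest-point sampling of ``k`` vertices by geodesic distance.

    ``candidates`` restricts both the sampled set and the distance support
    (distances run on the full graph).  The first point is ``start`` (default:
    the lowest candidate index).
    """
    candidates = np.asarray(candidates)
    if k > candidates.size:
        raise ValueError("cannot sample more points than candidates")
    first = candidates[0] if start is None else start
    chosen = [int(first)]
    dmin = dijkstra(graph, indices=first, directed=False)
    for _ in range(k - 1):
        sub = dmin[candidates]
        nxt = int(candidates[np.argmax(sub)])
        chosen.append(nxt)
        dmin = np.minimum(dmin, dijkstra(graph, indices=nxt, directed=False))
    return np.array(chosen)


def is_connected_subset(graph: sparse.csr_matrix, subset: np.ndarray) -> bool:
    """Whether the induced subgraph of ``subset`` vertices is one component."""
    subset = np.asarray(subset)
    if subset.size == 0:
        return False
    sub = graph[np.ix_(subset, subset)]
    n_comp, _ = connected_components(sub, directed=False)
    return n_comp == 1
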