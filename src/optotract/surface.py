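"""Triangulated cortical surface with per-vertex region labels.

All geometry is in world millimetres.  The surface is the common domain for
tractography terminal maps, histology fluorescence maps and their local
correlation, so it also owns the geodesic machinery those maps share.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

log = logging.getLogger("optotract")


class SurfaceError(ValueError):
    """Raised for inconsistent or badly oriented meshes."""


@dataclasses.dataclass
class LabeledSurface:
    """Manifold triangle mesh with integer region labels per vertex.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    triangles : (F, 3) int array of vertex indices, consistently wound
    vertex_labels : (V,) int array, 0 meaning unlabeled
    vertex_normals : (V, 3) unit outward normals; computed if None
    vertex_areas : (V,) mm^2, one third of incident triangle area; computed
        if None
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_labels: np.ndarray
    vertex_normals: np.ndarray | None = None
    vertex_areas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SurfaceError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise SurfaceError("triangles must be (F, 3)")
        if len(self.vertex_labels) != len(self.vertices):
            raise SurfaceError(
                "label array length does not match vertex count "
                f"({len(self.vertex_labels)} vs {len(self.vertices)})"
            )
        if not np.isfinite(self.vertices).all():
            raise SurfaceError("non-finite vertex coordinates")
        self._check_orientation()
        if self.vertex_normals is None:
            self.vertex_normals = self._compute_vertex_normals()
        else:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)
            norms = np.linalg.norm(self.vertex_normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise SurfaceError("supplied vertex normals are not unit length")
        if self.vertex_areas is None:
            self.vertex_areas = self._compute_vertex_areas()
        else:
            self.vertex_areas = np.asarray(self.vertex_areas, dtype=float)
        self._mesh: trimesh.Trimesh | None = None
        self._kdtree: cKDTree | None = None
        self._edge_graph = None
        self._neighborhood_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    # -- derived geometry -------------------------------------------------

    def _face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        tri = self.vertices[self.triangles]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        double_area = np.linalg.norm(cross, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / double_area[:, None]
        normals[double_area == 0] = 0.0
        return normals, double_area / 2.0

    def _compute_vertex_normals(self) -> np.ndarray:
        face_n, face_a = self._face_normals_areas()
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], face_n * face_a[:, None])
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        return vn / norms[:, None]

    def _compute_vertex_areas(self) -> np.ndarray:
        _, face_a = self._face_normals_areas()
        va = np.zeros(len(self.vertices))
        for k in range(3):
            np.add.at(va, self.triangles[:, k], face_a / 3.0)
        return va

    def _check_orientation(self) -> None:
        # Every interior edge of a consistently wound manifold appears once
        # per direction; a flipped triangle duplicates a directed edge.
        tri = self.triangles
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            if key in directed:
                raise SurfaceError(
                    f"inconsistent winding: directed edge {key} repeated"
                )
            directed[key] = True

    # -- cached helpers ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_area(self) -> float:
        return float(self.vertex_areas.sum())

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.triangles, process=False
            )
        return self._mesh

    @property
    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.vertices)
        return self._kdtree

    def region_labels(self) -> np.ndarray:
        labels = np.unique(self.vertex_labels)
        return labels[labels != 0]

    def region_vertices(self, region: int) -> np.ndarray:
        idx = np.flatnonzero(self.vertex_labels == region)
        if idx.size == 0:
            raise KeyError(f"region {region} not present on surface")
        return idx

    def region_area(self, region: int) -> float:
        return float(self.vertex_areas[self.region_vertices(region)].sum())

    # -- geodesics --------------------------------------------------------

    def edge_graph(self):
        """Sparse symmetric graph of mesh edges weighted by Euclidean length."""
        if self._edge_graph is None:
            tri = self.triangles
            i = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
            j = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
            # deduplicate (an interior edge belongs to two triangles; COO
            # duplicate entries would otherwise be summed by tocsr)
            pairs = np.unique(
                np.sort(np.column_stack([i, j]), axis=1), axis=0
            )
            i, j = pairs[:, 0], pairs[:, 1]
            w = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
            n = self.n_vertices
            g = coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
            self._edge_graph = g.tocsr()
        return self._edge_graph

    def geodesic_neighborhoods(self, radius_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Vertices within graph-geodesic ``radius_mm`` of each vertex.

        Returns ``(indptr, indices)`` in CSR layout: the neighborhood of
        vertex ``v`` (including ``v`` itself) is
        ``indices[indptr[v]:indptr[v + 1]]``.  Distances follow shortest
        paths along mesh edges (Dijkstra), a good approximation of surface
        geodesics whenever the radius exceeds the edge length.
        """
        if radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        key = round(float(radius_mm), 9)
        if key not in self._neighborhood_cache:
            dist = dijkstra(self.edge_graph(), directed=False, limit=radius_mm)
            rows, cols = np.nonzero(np.isfinite(dist))
            keep = dist[rows, cols] <= radius_mm
            rows, cols = rows[keep], cols[keep]
            order = np.argsort(rows, kind="stable")
            rows, cols = rows[order], cols[order]
            indptr = np.searchsorted(rows, np.arange(self.n_vertices + 1))
            self._neighborhood_cache[key] = (indptr, cols)
        return self._neighborhood_cache[key]

    @property
    def _face_tree(self) -> cKDTree:
        if getattr(self, "_face_tree_", None) is None:
            centroids = self.vertices[self.triangles].mean(axis=1)
            self._face_tree_ = cKDTree(centroids)
        return self._face_tree_

    def closest_points(
        self, points: np.ndarray, k_candidates: int = 12
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest mesh points, distances and face ids for query ``points``.

        Exact point-to-triangle projection over the ``k_candidates`` faces
        with nearest centroids (candidate search via a KD-tree; adequate
        for meshes with roughly uniform triangle size).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k_candidates, len(self.triangles))
        _, cand = self._face_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        tris = self.vertices[self.triangles]
        best_d = np.full(len(points), np.inf)
        best_pt = np.zeros_like(points)
        best_face = np.zeros(len(points), dtype=np.int64)
        for col in range(cand.shape[1]):
            faces = cand[:, col]
            close = trimesh.triangles.closest_point(tris[faces], points)
            d = np.linalg.norm(points - close, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_pt[better] = close[better]
            best_face[better] = faces[better]
        return best_pt, best_d, best_face

    @property
    def face_normals(self) -> np.ndarray:
        if getattr(self, "_face_normals_", None) is None:
            self._face_normals_, _ = self._face_normals_areas()
        return self._face_normals_

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the surface: positive on the outward side.

        Uses the offset from the closest mesh point projected on the face
        normal, which is well defined for open sheets (no winding numbers).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        closest, dist, face_id = self.closest_points(points)
        side = np.einsum("ij,ij->i", points - closest, self.face_normals[face_id])
        return np.where(side >= 0, dist, -dist)

    def interpolate_normal(self, point: np.ndarray, face_id: int) -> np.ndarray:
        """Unit outward normal at ``point`` on face ``face_id``, interpolated
        barycentrically from the vertex normals."""
        tri = self.triangles[face_id]
        bary = trimesh.triangles.points_to_barycentric(
            self.vertices[tri][None], np.asarray(point, dtype=float)[None]
        )[0]
        n = (self.vertex_normals[tri] * bary[:, None]).sum(axis=0)
        return n / np.linalg.norm(n)

    def nearest_vertex_of_face(self, point: np.ndarray, face_id: int) -> int:
        tri = self.triangles[face_id]
        d = np.linalg.norm(self.vertices[tri] - point, axis=1)
        return int(tri[int(np.argmin(d))])

    def validate(self) -> None:
        """Re-run the structural invariants (cheap; raises SurfaceError)."""
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SurfaceError("vertex normals are not unit length")
        _, face_a = self._face_normals_areas()
        if not np.isclose(self.vertex_areas.sum(), face_a.sum(), rtol=1e-6):
            raise SurfaceError("vertex areas do not sum to total triangle area")


def check_labels(labels: Iterable[int], n_vertices: int) -> np.ndarray:
    labels = np.asarray(list(labels), dtype=np.int64)
    if len(labels) != n_vertices:
        raise SurfaceError("label array length does not match vertex count")
    return labels
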