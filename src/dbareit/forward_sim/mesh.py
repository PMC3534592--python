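"""Triangular meshes of the unit/physical disk.

Meshes are built from concentric rings of nodes (ring ``i`` of ``nr`` carries
roughly ``2*pi*i`` nodes, so triangles stay close to equilateral) and
triangulated with a Delaunay pass; the disk is convex, so the Delaunay
triangulation covers exactly the polygon through the boundary nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["Mesh2D", "make_disk_mesh"]


@dataclass
class Mesh2D:
    """Conforming triangulation of a disk.

    Attributes
    ----------
    nodes : (N, 2) float array
        Node coordinates, in the length units of the domain radius.
    elements : (E, 3) int array
        Triangles as node-index triples, all counter-clockwise.
    boundary_edges : (B, 2) int array
        Boundary edges ordered counter-clockwise into one closed loop.
    radius : float
        Radius of the meshed disk.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_edges: np.ndarray
    radius: float = 1.0
    _centroids: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.nodes[self.elements].mean(axis=1)
        return self._centroids

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def boundary_nodes(self) -> np.ndarray:
        """Boundary node indices in counter-clockwise order."""
        return self.boundary_edges[:, 0]

    def scaled(self, factor: float) -> "Mesh2D":
        return Mesh2D(
            nodes=self.nodes * factor,
            elements=self.elements.copy(),
            boundary_edges=self.boundary_edges.copy(),
            radius=self.radius * factor,
        )


def _ring_points(radius: float, n_rings: int, n_boundary: int) -> np.ndarray:
    pts = [np.zeros((1, 2))]
    for i in range(1, n_rings + 1):
        r_i = radius * i / n_rings
        n_i = max(4, int(round(n_boundary * i / n_rings)))
        if i == n_rings:
            n_i = n_boundary
        theta = 2.0 * np.pi * np.arange(n_i) / n_i
        # stagger interior rings by half a step to avoid collinear slivers
        if i < n_rings:
            theta = theta + np.pi / n_i
        pts.append(np.column_stack([r_i * np.cos(theta), r_i * np.sin(theta)]))
    return np.vstack(pts)


def make_disk_mesh(
    radius: float,
    target_elements: int,
    n_boundary: int | None = None,
) -> Mesh2D:
    """Triangulate the disk of the given radius.

    Parameters
    ----------
    radius : float
        Disk radius, > 0.
    target_elements : int
        Requested triangle count (>= 100); the result is within ~30%.
    n_boundary : int, optional
        Exact number of equally spaced boundary nodes.  Pass a multiple of
        the electrode count so electrode arcs align with mesh edges.
    """
    if radius <= 0:
        raise ValueError(f"disk radius must be positive, got {radius}")
    if target_elements < 100:
        raise ValueError("target_elements must be >= 100")

    if n_boundary is None:
        n_rings = max(3, int(round(np.sqrt(target_elements / (2.0 * np.pi)))))
        n_boundary = int(round(2.0 * np.pi * n_rings))
    else:
        if n_boundary < 8:
            raise ValueError("n_boundary must be >= 8")
        n_rings = max(2, int(round(target_elements / n_boundary)))

    # triangulate at unit radius and scale afterwards so meshes of different
    # radii are exactly similar (Delaunay tie-breaking is scale-sensitive)
    pts = _ring_points(1.0, n_rings, n_boundary)
    tri = Delaunay(pts)
    pts = pts * radius
    elements = tri.simplices.copy()

    # enforce CCW orientation
    p = pts[elements]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    flip = areas < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    # drop degenerate slivers (zero area), if any
    keep = np.abs(areas) > 1e-14 * radius**2
    elements = elements[keep]

    boundary = _ordered_boundary(pts, elements)
    return Mesh2D(nodes=pts, elements=elements, boundary_edges=boundary, radius=radius)


def _ordered_boundary(pts: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Edges appearing in exactly one triangle, ordered CCW by angle."""
    edges = np.vstack(
        [elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bedges = edges[idx[counts == 1]]
    ang = np.arctan2(
        pts[bedges].mean(axis=1)[:, 1], pts[bedges].mean(axis=1)[:, 0]
    )
    order = np.argsort(ang)
    bedges = bedges[order]
    # orient each edge CCW (cross product of endpoints positive)
    cross = (
        pts[bedges[:, 0], 0] * pts[bedges[:, 1], 1]
        - pts[bedges[:, 0], 1] * pts[bedges[:, 1], 0]
    )
    swap = cross < 0
    bedges[swap] = bedges[swap][:, ::-1]
    return bedges
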