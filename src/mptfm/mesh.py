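"""Closed triangulated particle surfaces and their morphometrics.

A :class:`SurfaceMesh` is a star-shaped closed surface described by radii
along quasi-uniform directions about a center.  Triangulation topology comes
from the convex hull of the unit direction vectors and is reused for the
true (possibly non-convex) radii.  Derived quantities: surface area ``S``,
volume ``V``, sphericity ``Psi = pi^(1/3) (6 V)^(2/3) / S``,
volume-equivalent radius ``R_eq = (3V / 4 pi)^(1/3)``, median radius
``R_med``, per-vertex radial deviation and principal/mean curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from mptfm.geometry import cartesian_to_spherical, spherical_to_cartesian


@dataclass
class SurfaceMesh:
    """Closed, outward-oriented triangulated surface with per-vertex scalars."""

    vertices: np.ndarray  # (N, 3) um, absolute frame
    faces: np.ndarray  # (M, 3) int
    center: np.ndarray  # (3,) um; origin of the radial parameterization
    vertex_data: dict = field(default_factory=dict)
    radial_function: Callable | None = None  # optional analytic r(theta, phi)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.center = np.asarray(self.center, dtype=float)
        self._tm = None
        self._tree = None

    # -- construction -------------------------------------------------------
    @classmethod
    def from_directions(
        cls, directions: np.ndarray, radii: np.ndarray, center=(0.0, 0.0, 0.0),
        radial_function: Callable | None = None,
    ) -> "SurfaceMesh":
        """Build a star-shaped mesh from unit directions and radii.

        The hull of the *unit* directions provides the topology; outward
        orientation is enforced (positive signed volume).
        """
        directions = np.asarray(directions, dtype=float)
        radii = np.asarray(radii, dtype=float)
        if np.any(radii <= 0):
            raise ValueError("radii must be positive")
        hull = trimesh.convex.convex_hull(directions)
        # hull may reorder/merge vertices; map back to input directions
        tree = cKDTree(directions)
        _, idx = tree.query(hull.vertices)
        faces = idx[hull.faces]
        verts = np.asarray(center, float) + directions * radii[:, None]
        mesh = cls(verts, faces, np.asarray(center, float),
                   radial_function=radial_function)
        if mesh.volume < 0:
            mesh.faces = mesh.faces[:, ::-1]
            mesh._tm = None
        return mesh

    # -- cached helpers ------------------------------------------------------
    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.vertices - self.center, axis=1)

    @property
    def angles(self):
        """Per-vertex ``(theta, phi)`` about the center."""
        _, th, ph = cartesian_to_spherical(self.vertices - self.center)
        return th, ph

    @property
    def directions(self) -> np.ndarray:
        d = self.vertices - self.center
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    # -- morphometrics -------------------------------------------------------
    @property
    def area(self) -> float:
        return float(self.trimesh.area)

    @property
    def volume(self) -> float:
        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        return float(tm.volume)

    @property
    def sphericity(self) -> float:
        v, s = abs(self.volume), self.area
        return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / s)

    @property
    def r_equivalent(self) -> float:
        return float((3.0 * abs(self.volume) / (4.0 * np.pi)) ** (1.0 / 3.0))

    @property
    def r_median(self) -> float:
        return float(np.median(self.radii))

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of adjacent triangle areas)."""
        fa = self.trimesh.area_faces
        va = np.zeros(len(self.vertices))
        np.add.at(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    @property
    def vertex_adjacency(self) -> csr_matrix:
        n = len(self.vertices)
        e = self.trimesh.edges_unique
        data = np.ones(2 * len(e), dtype=bool)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    # -- field evaluation ----------------------------------------------------
    def radial_on_grid(self, theta, phi) -> np.ndarray:
        """Radii about the center on a (theta x phi) tensor grid.

        Uses the attached analytic radial function when present; otherwise
        inverse-distance interpolation of the 4 nearest mesh directions.
        """
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        th = theta[:, None] * np.ones_like(phi)[None, :]
        ph = np.ones_like(theta)[:, None] * phi[None, :]
        if self.radial_function is not None:
            return np.asarray(self.radial_function(th, ph), dtype=float)
        pts = spherical_to_cartesian(th.ravel(), ph.ravel())
        return self._interp_radii(pts).reshape(th.shape)

    def _interp_radii(self, unit_points: np.ndarray) -> np.ndarray:
        if self._tree is None:
            self._tree = cKDTree(self.directions)
        dist, idx = self._tree.query(unit_points, k=4)
        w = 1.0 / np.maximum(dist, 1e-9)
        r = self.radii[idx]
        return np.sum(w * r, axis=1) / np.sum(w, axis=1)

    def mask_on_grid(self, vertex_mask: np.ndarray, theta, phi) -> np.ndarray:
        """Nearest-vertex transfer of a per-vertex boolean to a tensor grid."""
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        th = theta[:, None] * np.ones_like(phi)[None, :]
        ph = np.ones_like(theta)[:, None] * phi[None, :]
        pts = spherical_to_cartesian(th.ravel(), ph.ravel())
        if self._tree is None:
            self._tree = cKDTree(self.directions)
        _, idx = self._tree.query(pts)
        return np.asarray(vertex_mask, bool)[idx].reshape(th.shape)

    # -- derived per-vertex fields ------------------------------------------
    def compute_vertex_fields(self, reference: str = "median") -> None:
        """Attach radial deviation and curvature fields to ``vertex_data``.

        ``reference``: ``'median'`` (deviation maps) or
        ``'volume_equivalent'`` (elasticity reference).  Curvatures come from
        a local quadric fit over the 2-ring neighborhood in each vertex
        tangent frame; sign convention: a sphere has ``H = +1/R``.
        """
        r_ref = self.r_median if reference == "median" else self.r_equivalent
        self.vertex_data["radial_deviation"] = self.radii - r_ref
        k1, k2, ok = _principal_curvatures(self)
        self.vertex_data["k1"] = k1
        self.vertex_data["k2"] = k2
        self.vertex_data["mean_curvature"] = 0.5 * (k1 + k2)
        self.vertex_data["curvature_valid"] = ok


def _principal_curvatures(mesh: SurfaceMesh):
    """Principal curvatures by quadric fitting over 2-ring neighborhoods."""
    verts = mesh.vertices
    n = len(verts)
    adj = mesh.vertex_adjacency
    two_ring = (adj @ adj + adj).tolil().rows  # includes self via adj@adj
    normals = np.asarray(mesh.trimesh.vertex_normals)
    k1 = np.zeros(n)
    k2 = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        nb = np.array(two_ring[i])
        nb = nb[nb != i]
        if nb.size < 5:
            ok[i] = False
            continue
        nrm = normals[i]
        # tangent frame
        t1 = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(nrm, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nrm, t1)
        rel = verts[nb] - verts[i]
        x = rel @ t1
        y = rel @ t2
        h = rel @ nrm
        A = np.column_stack([x**2, x * y, y**2, x, y])
        try:
            coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        except np.linalg.LinAlgError:
            ok[i] = False
            continue
        a, b, c, d, e = coef
        # Weingarten map with first-fundamental-form correction
        denom = np.sqrt(1.0 + d**2 + e**2)
        E = 1.0 + d**2
        F = d * e
        G = 1.0 + e**2
        II = np.array([[2.0 * a, b], [b, 2.0 * c]]) / denom
        I = np.array([[E, F], [F, G]])
        S = np.linalg.solve(I, II)
        ev = np.linalg.eigvals(S).real
        # outward normal: height of neighbors is negative on a sphere,
        # so flip sign to make the sphere's curvature +1/R
        kk = -np.sort(ev)[::-1]
        k1[i], k2[i] = np.sort(kk)[::-1]
    return k1, k2, ok
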