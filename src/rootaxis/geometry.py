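"""Geometry primitives shared by every stage of the root-axis pipeline.

All coordinates are millimetres in a right-handed frame.  The central
abstractions are :class:`TriangleMesh` (crowns, roots, isosurfaces),
:class:`Line3D` (a tooth's long axis, undirected), :class:`Plane`
(cross-section slicing support) and :class:`OutlineLoop` (a closed
root outline drawn on a slice).

The operations here implement the measurement primitives of the study:
orthogonal 3D line fitting, inter-axis angles, mesh/plane cross sections,
equidistant outline landmarking and area-uniform surface sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "TriangleMesh",
    "Line3D",
    "Plane",
    "OutlineLoop",
    "GeometryError",
    "DegeneracyWarning",
    "best_fit_line",
    "angle_between_lines",
    "plane_mesh_intersection",
    "equidistant_landmarks",
    "surface_sample_uniform",
]


class GeometryError(ValueError):
    """Raised for invalid or degenerate geometric input."""


class DegeneracyWarning(UserWarning):
    """Emitted when an operation hits a near-degenerate configuration
    and resolves it with a deterministic tie-break."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Indexed triangle surface (vertices in mm).

    Invariants (checked by :meth:`validate`): all face indices are in
    range, no face repeats a vertex, and no face has (near-)zero area.
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates per face."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def bounds(self) -> np.ndarray:
        """(2, 3) axis-aligned min/max corners."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def boundary_edge_count(self) -> int:
        """Number of edges used by exactly one face (0 for watertight)."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int((counts == 1).sum())

    def is_watertight(self) -> bool:
        return self.n_faces > 0 and self.boundary_edge_count() == 0

    def validate(self, zero_area_tol: float = 1e-12) -> None:
        if self.n_vertices == 0 or self.n_faces == 0:
            raise GeometryError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise GeometryError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise GeometryError("face with repeated vertex index")
        if np.any(self.face_areas() <= zero_area_tol):
            raise GeometryError("zero-area face")

    # -- conversions / transforms -------------------------------------------

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return TriangleMesh(v, self.faces.copy())

    def translated(self, offset: Sequence[float]) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces.copy())

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    @staticmethod
    def concatenate(meshes: Sequence["TriangleMesh"]) -> "TriangleMesh":
        verts, faces, offset = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            offset += m.n_vertices
        return TriangleMesh(np.vstack(verts), np.vstack(faces))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{what} has zero length")
    return v / n


@dataclass
class Line3D:
    """Undirected 3D line: ``anchor + t * direction``.

    ``direction`` and ``-direction`` denote the same line; all angle
    computations treat the line as axial.
    """

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)
        self.direction = _unit(self.direction, "line direction")

    def point_at(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction

    def distance_to_point(self, p: np.ndarray) -> float:
        d = np.asarray(p, float) - self.anchor
        return float(np.linalg.norm(d - (d @ self.direction) * self.direction))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Line3D":
        R = np.asarray(rotation, float)
        return Line3D(R @ self.anchor + np.asarray(translation, float), R @ self.direction)


@dataclass
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        self.normal = _unit(self.normal, "plane normal")

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane axes (deterministic)."""
        n = self.normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
        return u, np.cross(n, u)


@dataclass
class OutlineLoop:
    """Closed planar polyline (first point not repeated at the end)."""

    points: np.ndarray  # (k, 3)
    plane: Plane

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 3:
            raise GeometryError("outline loop needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def to_2d(self) -> np.ndarray:
        u, v = self.plane.basis()
        rel = self.points - self.plane.point
        return np.column_stack([rel @ u, rel @ v])

    def enclosed_area(self) -> float:
        """Absolute shoelace area of the projection onto its plane."""
        xy = self.to_2d()
        x, y = xy[:, 0], xy[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


# ---------------------------------------------------------------------------
# Line fitting and angles
# ---------------------------------------------------------------------------


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Fix the sign of an axial direction: largest-|component| positive,
    ties broken by the later index (lexicographic rule)."""
    idx = int(np.argmax(np.abs(d)))
    if d[idx] < 0:
        d = -d
    return d


def best_fit_line(points: np.ndarray) -> Line3D:
    """Total-least-squares line through a 3D point cloud.

    The anchor is the centroid; the direction is the principal axis of the
    centred points (first right singular vector), which minimises the sum
    of squared orthogonal distances.  Near-isotropic clouds (two equal
    leading singular values) produce a :class:`DegeneracyWarning` and a
    deterministic sign/tie-break.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 2:
        raise GeometryError("best_fit_line needs at least 2 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if not np.any(np.linalg.norm(centered, axis=1) > 1e-12):
        raise GeometryError("best_fit_line needs at least 2 distinct points")
    # SVD of the n x 3 centred matrix; right singular vectors are the
    # principal axes of the cloud.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) > 1 and s[0] - s[1] < 1e-9 * max(1.0, s[0]):
        warnings.warn(
            "near-isotropic point cloud: line direction resolved by a "
            "deterministic tie-break",
            DegeneracyWarning,
            stacklevel=2,
        )
    return Line3D(centroid, _canonical_direction(vt[0]))


def angle_between_lines(a: Line3D, b: Line3D) -> float:
    """Acute angle between two undirected lines, in degrees (0..90].

    Symmetric and invariant to flipping either direction.
    """
    c = abs(float(np.dot(a.direction, b.direction)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


# ---------------------------------------------------------------------------
# Plane/mesh cross sections
# ---------------------------------------------------------------------------

_ON_PLANE_TOL = 1e-9  # vertices closer than this are nudged off the plane
_CHAIN_GAP_MM = 0.5  # open chains with endpoint gap below this are closed


def plane_mesh_intersection(mesh: TriangleMesh, plane: Plane) -> list[OutlineLoop]:
    """Cross-section outlines of a triangle mesh with a plane.

    Per-edge intersection points are chained into closed loops, returned
    ordered by descending enclosed area.  Vertices lying exactly on the
    plane are nudged by +1e-9 mm along the normal so every crossing is a
    clean edge crossing.  Open chains (non-watertight meshes) are closed
    when the endpoint gap is below 0.5 mm and discarded (with a warning)
    otherwise.
    """
    lo, hi = mesh.bounds()
    # quick reject: plane entirely outside the bounding box
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    d_corners = plane.signed_distance(corners)
    if d_corners.min() > 0 or d_corners.max() < 0:
        return []

    d = plane.signed_distance(mesh.vertices)
    d = np.where(np.abs(d) < _ON_PLANE_TOL, _ON_PLANE_TOL, d)  # robustness nudge

    f = mesh.faces
    df = d[f]  # (m, 3)
    crossing = (df.min(axis=1) < 0) & (df.max(axis=1) > 0)
    if not crossing.any():
        return []

    # Each crossing face cuts exactly two of its edges (no on-plane vertices
    # after the nudge).  Intersections are computed per *unique* edge so
    # neighbouring faces chain through bit-identical points.
    edge_pairs = ((0, 1), (1, 2), (2, 0))
    seg_edges = []  # per crossing face: the two crossed edge keys
    edge_points: dict[tuple[int, int], np.ndarray] = {}
    for fi in np.nonzero(crossing)[0]:
        ids = f[fi]
        crossed = []
        for a, b in edge_pairs:
            va, vb = ids[a], ids[b]
            if d[va] * d[vb] < 0:
                key = (va, vb) if va < vb else (vb, va)
                if key not in edge_points:
                    ka, kb = key
                    t = d[ka] / (d[ka] - d[kb])
                    edge_points[key] = mesh.vertices[ka] + t * (
                        mesh.vertices[kb] - mesh.vertices[ka]
                    )
                crossed.append(key)
        if len(crossed) == 2:
            seg_edges.append(tuple(crossed))

    # chain segments: adjacency between edge keys
    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in seg_edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)

    visited: set[tuple[int, int]] = set()
    loops: list[OutlineLoop] = []
    for start in adjacency:
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        # walk forward
        while True:
            nxt = [e for e in adjacency[chain[-1]] if e not in visited]
            if not nxt:
                break
            chain.append(nxt[0])
            visited.add(nxt[0])
        # walk backward from the start (handles open chains)
        while True:
            prv = [e for e in adjacency[chain[0]] if e not in visited]
            if not prv:
                break
            chain.insert(0, prv[0])
            visited.add(prv[0])
        pts = np.array([edge_points[e] for e in chain])
        if len(pts) < 3:
            continue
        closed = chain[-1] in adjacency.get(chain[0], []) and len(chain) > 2
        if not closed:
            gap = np.linalg.norm(pts[0] - pts[-1])
            if gap >= _CHAIN_GAP_MM:
                warnings.warn(
                    f"discarding open cross-section chain (endpoint gap {gap:.3f} mm)",
                    DegeneracyWarning,
                    stacklevel=2,
                )
                continue
        loops.append(OutlineLoop(pts, plane))

    loops.sort(key=lambda lp: lp.enclosed_area(), reverse=True)
    return loops


# ---------------------------------------------------------------------------
# Outline landmarking
# ---------------------------------------------------------------------------


def equidistant_landmarks(loop: OutlineLoop, k: int) -> np.ndarray:
    """``k`` points at equal arc-length spacing along a closed outline.

    The walk starts at the loop vertex with the smallest x coordinate
    (ties broken by y, then z) so the result is deterministic regardless
    of how the outline was chained.
    """
    if k < 3:
        raise GeometryError("need at least 3 landmarks per outline")
    pts = loop.points
    # deterministic start vertex
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    start = order[0]
    poly = np.vstack([pts[start:], pts[:start], pts[start : start + 1]])
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise GeometryError("degenerate outline with zero perimeter")
    targets = np.arange(k) * perimeter / k
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return poly[idx] + frac[:, None] * (poly[idx + 1] - poly[idx])


# ---------------------------------------------------------------------------
# Surface sampling
# ---------------------------------------------------------------------------


def surface_sample_uniform(
    mesh: TriangleMesh,
    n: int,
    seed: int,
    exclude: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Draw ``n`` area-uniform points on a mesh surface, deterministically.

    Faces are chosen with probability proportional to area (after removing
    faces whose centroid satisfies ``exclude``), and the point within each
    face is barycentric-uniform (square-root warp).

    Parameters
    ----------
    exclude
        Optional vectorised predicate over face centroids, shape (m, 3) ->
        boolean mask of faces to drop.
    """
    if n < 1:
        raise GeometryError("need at least 1 sample")
    mesh.validate()
    keep = np.ones(mesh.n_faces, dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude(mesh.face_centroids()), dtype=bool)
    areas = mesh.face_areas() * keep
    total = areas.sum()
    if total <= 0:
        raise GeometryError("exclusion predicate removed every face")
    rng = np.random.default_rng(seed)
    fidx = rng.choice(mesh.n_faces, size=n, p=areas / total)
    tri = mesh.triangles[fidx]
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a = 1.0 - r1
    b = r1 * (1.0 - r2)
    c = r1 * r2
    return a[:, None] * tri[:, 0] + b[:, None] * tri[:, 1] + c[:, None] * tri[:, 2]
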