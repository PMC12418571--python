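"""Exact cuboid overlap by iterative half-space clipping.

The reference voxel is an axis-aligned cuboid described by six planes,
each splitting space into a "definitely outside" and a "potentially
inside" half.  The moved voxel (the same cuboid pushed through a
rigid-body transform) is clipped against the six planes in turn: the
part surviving all six cuts is the overlapping remnant, a convex
polytope whose volume — obtained by tetrahedral decomposition of its
convex hull — is related to the reference voxel's volume to give the
overlap fraction.

The clipping itself is Sutherland–Hodgman polygon clipping lifted to
3-D: every face of the convex polyhedron is clipped edge-by-edge with
linear interpolation at the plane crossings, and the cut openings are
closed with a new cap face.  A Monte-Carlo estimator over the moved
cuboid is provided as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .rigid_transforms import RigidTransform

#: vertices closer than this (mm) are merged; vertices within this
#: distance of a cutting plane count as kept (inclusive), so shared
#: faces do not lose slivers to round-off.
PLANE_TOL = 1e-9


@dataclass
class HalfSpace:
    """A half-space ``{x : (x - point) · normal >= 0}``.

    ``normal`` is a unit vector pointing toward the kept
    ("potentially inside") side.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-12:
            if norm == 0:
                raise ValueError("half-space normal must be nonzero")
            self.normal = self.normal / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive on the kept side."""
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class ConvexPolytope:
    """A convex 3-D body held as its vertex set plus face polygons.

    ``faces`` lists each planar face as an ordered ring of vertex
    coordinates; it is maintained through clipping so no hull
    reconstruction is needed mid-pipeline.  An empty vertex set is a
    legitimate polytope of volume zero.
    """

    vertices: np.ndarray
    faces: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0

    def volume(self) -> float:
        return polytope_volume(self)


def make_cuboid(center, dims) -> ConvexPolytope:
    """Axis-aligned cuboid at ``center`` with edge lengths ``dims`` (mm)."""
    center = np.asarray(center, dtype=float)
    dims = np.asarray(dims, dtype=float)
    if center.shape != (3,) or dims.shape != (3,):
        raise ValueError("center and dims must be 3-vectors")
    if np.any(dims <= 0):
        raise ValueError(f"cuboid dims must be positive, got {tuple(dims)}")
    h = dims / 2.0
    signs = np.array(
        [
            [-1, -1, -1],
            [+1, -1, -1],
            [+1, +1, -1],
            [-1, +1, -1],
            [-1, -1, +1],
            [+1, -1, +1],
            [+1, +1, +1],
            [-1, +1, +1],
        ],
        dtype=float,
    )
    verts = center + signs * h
    # faces as ordered rings (orientation is irrelevant to the volume path)
    idx_faces = [
        [0, 1, 2, 3],  # bottom (z-)
        [4, 5, 6, 7],  # top (z+)
        [0, 1, 5, 4],  # y-
        [3, 2, 6, 7],  # y+
        [0, 3, 7, 4],  # x-
        [1, 2, 6, 5],  # x+
    ]
    faces = [verts[idx] for idx in idx_faces]
    return ConvexPolytope(vertices=verts, faces=faces)


def cuboid_halfspaces(center, dims) -> list[HalfSpace]:
    """The six inward-facing half-spaces whose intersection is the cuboid."""
    center = np.asarray(center, dtype=float)
    h = np.asarray(dims, dtype=float) / 2.0
    planes = []
    for ax in range(3):
        for sign in (-1.0, +1.0):
            normal = np.zeros(3)
            normal[ax] = -sign  # inward
            point = center.copy()
            point[ax] += sign * h[ax]
            planes.append(HalfSpace(point=point, normal=normal))
    return planes


def _dedupe(points: np.ndarray, tol: float = PLANE_TOL) -> np.ndarray:
    if len(points) == 0:
        return points.reshape(0, 3)
    out = [points[0]]
    for p in points[1:]:
        if all(np.max(np.abs(p - q)) > tol for q in out):
            out.append(p)
    return np.asarray(out)


def _cap_face(points: list, normal: np.ndarray) -> np.ndarray | None:
    """Order the cut points into a convex ring lying in the cutting plane."""
    pts = _dedupe(np.asarray(points))
    if len(pts) < 3:
        return None
    centroid = pts.mean(axis=0)
    # orthonormal in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = pts - centroid
    ang = np.arctan2(rel @ v, rel @ u)
    return pts[np.argsort(ang)]


def clip_halfspace(poly: ConvexPolytope, hs: HalfSpace, tol: float = PLANE_TOL) -> ConvexPolytope:
    """Clip a convex polytope with one half-space.

    Each face ring is clipped Sutherland–Hodgman style: vertices on
    the kept side survive, and every edge crossing the plane
    contributes the linearly interpolated intersection point.  The cut
    opening is closed with a planar cap face.  The empty polytope is a
    valid result.
    """
    if poly.is_empty:
        return ConvexPolytope(vertices=np.empty((0, 3)))
    if not poly.faces:
        poly = _rebuild_faces(poly)
        if poly.is_empty:
            return ConvexPolytope(vertices=np.empty((0, 3)))

    new_faces: list[np.ndarray] = []
    cap_points: list[np.ndarray] = []
    any_clipped = False
    for face in poly.faces:
        face = np.asarray(face, dtype=float)
        d = hs.signed_distance(face)
        inside = d >= -tol
        if inside.all():
            new_faces.append(face)
            continue
        any_clipped = True
        if not inside.any():
            continue
        out: list[np.ndarray] = []
        n = len(face)
        for i in range(n):
            a, b = face[i], face[(i + 1) % n]
            da, db = d[i], d[(i + 1) % n]
            a_in, b_in = inside[i], inside[(i + 1) % n]
            if a_in:
                out.append(a)
                if abs(da) <= tol:
                    cap_points.append(a)
            if a_in != b_in:
                t = da / (da - db)
                p = a + t * (b - a)
                out.append(p)
                cap_points.append(p)
        if len(out) >= 3:
            new_faces.append(np.asarray(out))

    if not any_clipped:
        return ConvexPolytope(
            vertices=poly.vertices.copy(), faces=[f.copy() for f in poly.faces]
        )
    cap = _cap_face(cap_points, hs.normal) if cap_points else None
    if cap is not None:
        new_faces.append(cap)
    if not new_faces:
        return ConvexPolytope(vertices=np.empty((0, 3)))
    verts = _dedupe(np.vstack(new_faces))
    return ConvexPolytope(vertices=verts, faces=new_faces)


def _rebuild_faces(poly: ConvexPolytope) -> ConvexPolytope:
    """Recover face rings from a bare vertex set via the convex hull."""
    verts = _dedupe(poly.vertices)
    if len(verts) < 4:
        return ConvexPolytope(vertices=verts)
    try:
        hull = ConvexHull(verts)
    except QhullError:
        return ConvexPolytope(vertices=verts)
    faces = [verts[simplex] for simplex in hull.simplices]
    return ConvexPolytope(vertices=verts[hull.vertices], faces=faces)


def polytope_volume(poly: ConvexPolytope) -> float:
    """Volume via tetrahedral decomposition of the convex hull.

    The remnant of a convex body cut by half-spaces is itself convex,
    so the hull of its vertices has exactly its volume.  Degenerate
    vertex sets (empty, point, segment, planar polygon) are legitimate
    "no 3-D overlap" outcomes and return 0.
    """
    verts = _dedupe(np.asarray(poly.vertices, dtype=float).reshape(-1, 3))
    if len(verts) < 4:
        return 0.0
    try:
        return float(ConvexHull(verts).volume)
    except QhullError:
        # coplanar / collinear vertex set
        return 0.0


def _moved_cuboid(T: RigidTransform, center, dims) -> ConvexPolytope:
    cuboid = make_cuboid(center, dims)
    verts = T.apply(cuboid.vertices)
    faces = [T.apply(f) for f in cuboid.faces]
    return ConvexPolytope(vertices=verts, faces=faces)


def overlap_fraction(T: RigidTransform, center, dims) -> float:
    """Fraction of the voxel volume still overlapping after motion ``T``.

    The cuboid at ``center`` with edge lengths ``dims`` is moved by
    ``T`` and clipped sequentially against its own six original
    half-spaces; the remnant volume is divided by the reference volume
    dx*dy*dz.  The identity transform short-circuits to exactly 1.
    """
    dims = np.asarray(dims, dtype=float)
    if np.any(dims <= 0):
        raise ValueError(f"voxel dims must be positive, got {tuple(dims)}")
    if np.max(np.abs(T.matrix - np.eye(4))) < 1e-14:
        return 1.0
    poly = _moved_cuboid(T, center, dims)
    for hs in cuboid_halfspaces(center, dims):
        poly = clip_halfspace(poly, hs)
        if poly.is_empty:
            return 0.0
    frac = polytope_volume(poly) / float(np.prod(dims))
    return min(1.0, max(0.0, frac))


def slab_excess_volumes(T: RigidTransform, center, dims, axis) -> tuple[float, float]:
    """Moved-cuboid volume beyond the reference slab along one axis.

    Returns ``(below, above)`` in mm^3: the parts of the moved cuboid
    strictly beyond the reference cuboid's two faces perpendicular to
    ``axis`` (the infinite slab's two outer half-spaces).  For an
    axial acquisition the z-axis slab separates in-plane from
    out-of-plane displacement.
    """
    axis_idx = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if axis_idx not in (0, 1, 2):
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    center = np.asarray(center, dtype=float)
    dims = np.asarray(dims, dtype=float)
    if np.any(dims <= 0):
        raise ValueError(f"voxel dims must be positive, got {tuple(dims)}")
    h = dims[axis_idx] / 2.0
    out = []
    for sign in (-1.0, +1.0):
        normal = np.zeros(3)
        normal[axis_idx] = sign  # outward: keep the part beyond the face
        point = center.copy()
        point[axis_idx] += sign * h
        poly = clip_halfspace(_moved_cuboid(T, center, dims), HalfSpace(point, normal))
        out.append(polytope_volume(poly))
    return out[0], out[1]


def mc_overlap_oracle(T: RigidTransform, center, dims, n_samples: int, seed: int) -> float:
    """Monte-Carlo overlap estimate — the independent testing oracle.

    Samples points uniformly inside the moved cuboid (uniform in the
    reference cuboid, then pushed through ``T``) and counts the
    fraction landing inside the reference cuboid.  The standard error
    is approximately ``sqrt(p (1-p) / n)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    center = np.asarray(center, dtype=float)
    dims = np.asarray(dims, dtype=float)
    rng = np.random.default_rng(seed)
    pts = center + (rng.random((n_samples, 3)) - 0.5) * dims
    moved = T.apply(pts)
    inside = np.all(np.abs(moved - center) <= dims / 2.0, axis=1)
    return float(inside.mean())
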