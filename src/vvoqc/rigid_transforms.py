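"""Rigid-body transforms from realignment parameters, and TD/STS.

A realignment parameter vector ``(tx, ty, tz, rx, ry, rz)`` (mm and
radians) maps to the homogeneous transform ``T(t) * Rx(rx) * Ry(ry) *
Rz(rz)`` — the SPM composition order, rotating about the world origin
with right-handed, counterclockwise-positive rotations.  Total
displacement (TD) takes the first volume as reference; scan-to-scan
displacement (STS) takes the immediately preceding one.  Because a
rotation translates material points in proportion to their distance
from the origin, displacement is evaluated at representative points on
a sphere of radius 65 mm (the average adult cortical distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RADIUS_MM = 65.0

_ORTHO_TOL = 1e-10


@dataclass
class RigidTransform:
    """A 4x4 homogeneous rigid-body transform in mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("rigid transform must be a 4x4 matrix")
        R = self.rotation
        if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHO_TOL:
            raise ValueError("rotation block is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation block must be proper (det +1)")
        if np.max(np.abs(self.matrix[3] - np.array([0, 0, 0, 1.0]))) > 0:
            raise ValueError("last row must be (0, 0, 0, 1)")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one 3-vector or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        m = np.eye(4)
        m[:3, :3] = R.T
        m[:3, 3] = -R.T @ self.translation
        return RigidTransform(m)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)


@dataclass
class DisplacementSeries:
    """Per-timepoint displacement in mm (TD or STS convention)."""

    values: np.ndarray
    mode: str
    radius: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("TD", "STS"):
            raise ValueError(f"mode must be TD or STS, got {self.mode!r}")


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def params_to_transform(p) -> RigidTransform:
    """6-vector (tx, ty, tz [mm], rx, ry, rz [rad]) -> rigid transform.

    Matrix is ``T(t) * Rx * Ry * Rz``; rotations are about the world
    origin of the parameter frame (what realignment reports), not the
    voxel center.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.shape != (6,):
        raise ValueError(f"expected 6 parameters, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("motion parameters must be finite")
    m = np.eye(4)
    m[:3, :3] = _rot_x(p[3]) @ _rot_y(p[4]) @ _rot_z(p[5])
    m[:3, 3] = p[:3]
    return RigidTransform(m)


def relative_transform(T_t: RigidTransform, T_ref: RigidTransform) -> RigidTransform:
    """Motion of timepoint t relative to a reference: ``T_t * T_ref^-1``."""
    return T_t.compose(T_ref.inverse())


def point_displacement(T: RigidTransform, point) -> float:
    """Euclidean displacement ``|T(p) - p|`` of a material point, mm."""
    point = np.asarray(point, dtype=float)
    return float(np.linalg.norm(T.apply(point) - point))


def _representative_points(radius: float) -> np.ndarray:
    r = float(radius)
    return np.array(
        [
            [+r, 0, 0],
            [-r, 0, 0],
            [0, +r, 0],
            [0, -r, 0],
            [0, 0, +r],
            [0, 0, -r],
        ]
    )


def displacement_series(
    series,
    mode: str = "STS",
    radius: float = DEFAULT_RADIUS_MM,
    aggregate: str = "median_points",
) -> DisplacementSeries:
    """Conventional TD or STS displacement per volume.

    Parameters
    ----------
    series : MotionSeries
        Realignment parameters.
    mode : {"TD", "STS"}
        Reference frame: first volume (TD) or preceding volume (STS).
    radius : float
        Lever-arm distance in mm at which rotations are converted to
        translation; default 65 mm.
    aggregate : {"median_points", "rss"}
        ``median_points``: median Euclidean displacement of the six
        representative points at ``radius`` (default, consistent with
        the VVO probe locations).  ``rss``: root-sum-square of the
        three translations and the three arc lengths ``theta * radius``,
        kept for comparability with simpler summary formulas.

    The first timepoint is 0 by convention in both modes.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("TD", "STS"):
        raise ValueError(f"mode must be TD or STS, got {mode!r}")
    if aggregate not in ("median_points", "rss"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    transforms = [params_to_transform(p) for p in series.params]
    pts = _representative_points(radius)
    values = np.zeros(len(transforms))
    for t in range(1, len(transforms)):
        ref = transforms[0] if mode == "TD" else transforms[t - 1]
        rel = relative_transform(transforms[t], ref)
        if aggregate == "median_points":
            disp = np.linalg.norm(rel.apply(pts) - pts, axis=1)
            values[t] = float(np.median(disp))
        else:
            p = np.asarray(series.params[t], dtype=float)
            q = np.asarray(series.params[0 if mode == "TD" else t - 1], dtype=float)
            d = p - q
            values[t] = float(np.sqrt(np.sum(d[:3] ** 2) + np.sum((d[3:] * radius) ** 2)))
    return DisplacementSeries(values=values, mode=mode, radius=radius)
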