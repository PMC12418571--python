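"""Per-timepoint voxel volume overlap metrics.

Motion effects are spatially heterogeneous — a rotation barely touches
voxels near its axis and sweeps distant ones — so overlap is probed at
six representative voxels on a sphere of radius 65 mm around the
image origin (anterior/posterior, right/left, superior/inferior, RAS
axes) and summarized by the per-timepoint median.

``TD_VVO`` measures overlap against the voxel's first-volume position
(slow drift); ``STS_VVO`` against its preceding-volume position
(motion spikes).  Both are percentages of the voxel volume.  The
out-of-plane series decomposes the *non*-overlapping volume into the
part that left the acquisition slab (through-plane, most harmful due
to spin-history effects) versus in-plane shifts; it is referenced to
the first volume since the acquisition plane is fixed over the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_motion import MotionSeries, VoxelSpec, PLANE_AXIS
from .polytope_geometry import overlap_fraction, slab_excess_volumes
from .rigid_transforms import (
    DEFAULT_RADIUS_MM,
    params_to_transform,
    relative_transform,
)

#: the eight isotropic sizes of the voxel-size sweep, mm
DEFAULT_SIZE_GRID = (4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5)

LOCATION_LABELS = ("A", "P", "R", "L", "S", "I")


def representative_centers(radius: float = DEFAULT_RADIUS_MM):
    """Six probe-voxel centers at ``radius`` mm from the origin.

    Returns an ordered mapping label -> center with RAS axes:
    A/P = (0, +/-r, 0), R/L = (+/-r, 0, 0), S/I = (0, 0, +/-r).
    The three antipodal pairs sum to the origin.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = float(radius)
    return {
        "A": np.array([0.0, +r, 0.0]),
        "P": np.array([0.0, -r, 0.0]),
        "R": np.array([+r, 0.0, 0.0]),
        "L": np.array([-r, 0.0, 0.0]),
        "S": np.array([0.0, 0.0, +r]),
        "I": np.array([0.0, 0.0, -r]),
    }


@dataclass
class VVOSeries:
    """TD_VVO / STS_VVO percentages per timepoint and location."""

    td_vvo: np.ndarray  # (n_volumes, n_locations), percent
    sts_vvo: np.ndarray
    td_vvo_median: np.ndarray  # (n_volumes,)
    sts_vvo_median: np.ndarray
    locations: tuple
    radius: float
    voxel: VoxelSpec


@dataclass
class OutOfPlaneSeries:
    """Percent of displaced (non-overlapping) volume that left the slab.

    Undefined when there is no displaced volume at all (no motion);
    those timepoints carry ``defined=False`` and NaN.  ``per_center``
    holds the unpooled per-location ratios for inspection.
    """

    values: np.ndarray  # percent, NaN where undefined
    defined: np.ndarray  # bool mask
    per_center: np.ndarray  # (n_volumes, n_locations), NaN where undefined
    plane: str
    locations: tuple


def _transforms(series: MotionSeries):
    return [params_to_transform(p) for p in series.params]


def compute_vvo(
    series: MotionSeries,
    voxel: VoxelSpec,
    radius: float = DEFAULT_RADIUS_MM,
    centers=None,
) -> VVOSeries:
    """Voxel volume overlap at the six representative voxels.

    For each timepoint t and probe center c, the voxel cuboid at c is
    moved by the relative transform (t vs first volume for TD_VVO, t
    vs preceding volume for STS_VVO) and clipped against its own
    unmoved copy; the remnant volume is expressed in percent.  The
    first timepoint is 100 by convention.  ``centers`` may override
    the probes with arbitrary locations (e.g. atlas region centers).
    """
    if centers is None:
        centers = representative_centers(radius)
    labels = tuple(centers.keys())
    pts = list(centers.values())
    dims = voxel.dims
    transforms = _transforms(series)
    n, k = len(transforms), len(pts)
    td = np.full((n, k), 100.0)
    sts = np.full((n, k), 100.0)
    for t in range(1, n):
        rel_td = relative_transform(transforms[t], transforms[0])
        rel_sts = relative_transform(transforms[t], transforms[t - 1])
        for j, c in enumerate(pts):
            td[t, j] = 100.0 * overlap_fraction(rel_td, c, dims)
            sts[t, j] = 100.0 * overlap_fraction(rel_sts, c, dims)
    return VVOSeries(
        td_vvo=td,
        sts_vvo=sts,
        td_vvo_median=np.median(td, axis=1),
        sts_vvo_median=np.median(sts, axis=1),
        locations=labels,
        radius=radius,
        voxel=voxel,
    )


def out_of_plane(
    series: MotionSeries,
    voxel: VoxelSpec,
    plane: str | None = None,
    radius: float = DEFAULT_RADIUS_MM,
    centers=None,
) -> OutOfPlaneSeries:
    """Proportion of displaced volume outside the acquisition slab.

    Reference is always the first volume.  Per timepoint, the moved
    voxel's volume beyond the two slab faces perpendicular to the
    through-plane axis (axial -> z, coronal -> y, sagittal -> x) is
    summed over the six probe centers and divided by the pooled total
    non-overlapping volume.  Pooling before the ratio keeps the value
    stable when individual probes barely move; per-center ratios are
    returned alongside.
    """
    plane = plane or voxel.plane
    if plane not in PLANE_AXIS:
        raise ValueError(f"unknown acquisition plane {plane!r}")
    axis = PLANE_AXIS[plane]
    if centers is None:
        centers = representative_centers(radius)
    labels = tuple(centers.keys())
    pts = list(centers.values())
    dims = voxel.dims
    vol = float(np.prod(dims))
    transforms = _transforms(series)
    n, k = len(transforms), len(pts)
    values = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    per_center = np.full((n, k), np.nan)
    for t in range(1, n):
        rel = relative_transform(transforms[t], transforms[0])
        oop_sum = 0.0
        nonov_sum = 0.0
        for j, c in enumerate(pts):
            overlap_vol = vol * overlap_fraction(rel, c, dims)
            below, above = slab_excess_volumes(rel, c, dims, axis)
            nonov = vol - overlap_vol
            oop_sum += below + above
            nonov_sum += nonov
            if nonov > 1e-12:
                per_center[t, j] = 100.0 * (below + above) / nonov
        if nonov_sum > 1e-12:
            values[t] = 100.0 * oop_sum / nonov_sum
            defined[t] = True
    return OutOfPlaneSeries(
        values=values, defined=defined, per_center=per_center, plane=plane, locations=labels
    )


def voxel_size_sweep(
    series: MotionSeries,
    sizes=DEFAULT_SIZE_GRID,
    radius: float = DEFAULT_RADIUS_MM,
    plane: str = "axial",
) -> pd.DataFrame:
    """Median TD_VVO / STS_VVO as a function of simulated voxel size.

    Re-runs the overlap computation on the same motion parameters for
    each voxel size; isotropic scalar sizes or (dx, dy, dz) triples
    are accepted.  Summary per size is the median over timepoints of
    the per-timepoint median across the six locations.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    rows = []
    for size in sizes:
        dims = (size, size, size) if np.isscalar(size) else tuple(size)
        voxel = VoxelSpec(dims=dims, plane=plane)
        vvo = compute_vvo(series, voxel, radius=radius)
        rows.append(
            {
                "dx_mm": dims[0],
                "dy_mm": dims[1],
                "dz_mm": dims[2],
                "td_vvo_median": float(np.median(vvo.td_vvo_median)),
                "sts_vvo_median": float(np.median(vvo.sts_vvo_median)),
            }
        )
    return pd.DataFrame(rows)
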