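"""Reading and writing realignment parameter files and QC reports.

Supported dialects:

- SPM ``rp_*.txt``: whitespace-separated, six floats per line, order
  ``tx ty tz rx ry rz`` (mm, radians) — the canonical internal order.
- FSL ``.par``: whitespace-separated, six floats per line, order
  ``rx ry rz tx ty tz`` (radians first); re-ordered on read.
- BIDS confounds TSV: tab-separated with a header row; columns
  ``trans_x trans_y trans_z rot_x rot_y rot_z`` (rotations in radians
  per the BIDS convention; a ``degrees`` override exists for
  nonconforming files).

The first row is taken as the reference volume's parameters (usually
zeros) and is used as given, never forced to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .report import QCReport

PLANES = ("axial", "coronal", "sagittal")

#: acquisition plane -> through-plane (slice-select) axis
PLANE_AXIS = {"axial": "z", "coronal": "y", "sagittal": "x"}

_BIDS_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class MotionSeries:
    """Per-volume rigid-body parameters: tx, ty, tz (mm), rx, ry, rz (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).reshape(-1, 6)
        if len(self.params) < 1:
            raise ValueError("a motion series needs at least one volume")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return len(self.params)

    def __len__(self) -> int:
        return len(self.params)


@dataclass
class VoxelSpec:
    """Voxel dimensions (mm), acquisition plane, and resolution label.

    ``label`` distinguishes the scanner's acquired grid spacing from a
    user-supplied effective resolution (data smoothness); the acquired
    size is the recommended reference.
    """

    dims: tuple
    plane: str = "axial"
    label: str = "acquired"

    def __post_init__(self) -> None:
        dims = tuple(float(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"voxel dims must be three positive values, got {self.dims}")
        self.dims = dims
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        if self.label not in ("acquired", "effective"):
            raise ValueError(f"label must be 'acquired' or 'effective', got {self.label!r}")

    @property
    def through_plane_axis(self) -> str:
        return PLANE_AXIS[self.plane]

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.dims))


def _parse_plain(path: Path, n_cols: int = 6) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != n_cols:
                raise ValueError(
                    f"{path}, line {lineno}: expected {n_cols} columns, found {len(tokens)}"
                )
            try:
                rows.append([float(tok) for tok in tokens])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric token ({exc})") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows)


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".par":
        return "fsl_par"
    if suffix == ".tsv":
        return "bids_tsv"
    with open(path) as fh:
        first = fh.readline()
    if "trans_x" in first or "rot_x" in first:
        return "bids_tsv"
    return "spm_rp"


def read_motion_file(path, dialect: str = "auto", degrees: bool = False) -> MotionSeries:
    """Read a realignment parameter file into canonical internal form.

    Parameters
    ----------
    path : path-like
    dialect : {"auto", "spm_rp", "fsl_par", "bids_tsv"}
        ``auto`` resolves from the file extension (``.par`` -> FSL,
        ``.tsv`` -> BIDS) and header sniffing.
    degrees : bool
        Treat rotations as degrees and convert (for nonconforming
        files); all dialects store radians by convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "spm_rp":
        data = _parse_plain(path)
    elif dialect == "fsl_par":
        data = _parse_plain(path)[:, [3, 4, 5, 0, 1, 2]]  # rot-first -> trans-first
    elif dialect == "bids_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _BIDS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing confound columns {missing}")
        data = df[_BIDS_COLUMNS].to_numpy(dtype=float)
        if len(data) == 0:
            raise ValueError(f"{path}: no data rows")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if degrees:
        data = data.copy()
        data[:, 3:] = np.deg2rad(data[:, 3:])
    return MotionSeries(params=data)


def write_motion_file(series: MotionSeries, path, dialect: str = "spm_rp") -> Path:
    """Write a motion series in any supported dialect (fixture/export use)."""
    path = Path(path)
    data = series.params
    if dialect == "spm_rp":
        np.savetxt(path, data, fmt="%.10e")
    elif dialect == "fsl_par":
        np.savetxt(path, data[:, [3, 4, 5, 0, 1, 2]], fmt="%.10e")
    elif dialect == "bids_tsv":
        pd.DataFrame(data, columns=_BIDS_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format="%.10e"
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_voxel_dims(nifti_path) -> tuple:
    """Voxel dimensions (dx, dy, dz) in mm from a NIfTI-1/2 header.

    Returns absolute values of the three spatial grid spacings; the
    4th (time) dimension is ignored.  No image data is loaded.
    """
    img = nib.load(str(nifti_path))
    zooms = np.abs(np.asarray(img.header["pixdim"][1:4], dtype=float))
    if np.any(~np.isfinite(zooms)) or np.any(zooms == 0):
        raise ValueError(f"{nifti_path}: header has missing or zero voxel spacing {tuple(zooms)}")
    return tuple(float(z) for z in zooms)


# -- report output ----------------------------------------------------------

_CSV_FLOAT_FMT = "%.17g"


def write_report(report: QCReport, path, format: str = "json") -> Path:
    """Write a QC report as nested JSON or a flat per-timepoint CSV.

    JSON round-trips losslessly through :func:`read_report`; CSV holds
    one row per timepoint with full float precision.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "meta": report.meta,
            "per_timepoint": {
                col: report.per_timepoint[col].tolist() for col in report.per_timepoint.columns
            },
            "summary": report.summary,
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "csv":
        report.per_timepoint.to_csv(path, index=False, float_format=_CSV_FLOAT_FMT)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path) -> QCReport:
    """Read back a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    return QCReport(
        meta=payload["meta"],
        per_timepoint=pd.DataFrame(payload["per_timepoint"]),
        summary=payload["summary"],
    )
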