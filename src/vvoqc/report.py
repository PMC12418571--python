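"""Structured QC report assembled from the per-module outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCATION_LABELS = ("A", "P", "R", "L", "S", "I")


@dataclass
class QCReport:
    """Everything one run computes, in machine-readable form.

    ``meta`` records the inputs and settings, ``per_timepoint`` holds
    one row per volume (TD, STS, six-location TD_VVO/STS_VVO, medians,
    out-of-plane percentage, censor flag), and ``summary`` holds the
    scalars recomputable from ``per_timepoint``.
    """

    meta: dict
    per_timepoint: pd.DataFrame
    summary: dict

    def __post_init__(self) -> None:
        if "n_volumes" in self.meta and len(self.per_timepoint) != self.meta["n_volumes"]:
            raise ValueError("per_timepoint length must equal n_volumes")


def build_report(
    series,
    voxel,
    radius: float = 65.0,
    censor_measure: str = "sts_vvo",
    censor_threshold: float = 55.0,
    thresholds=(90.0, 80.0, 55.0),
    meta_extra: dict | None = None,
) -> QCReport:
    """Run the full QC pipeline on one motion series.

    Computes conventional TD/STS displacement, the six-location
    TD_VVO/STS_VVO overlap series with medians, the out-of-plane
    proportion for the acquisition plane, quality labels, and the
    censoring indicator at ``censor_threshold`` percent.
    """
    from .calibration_quality import association_report, censor_regressor, classify
    from .rigid_transforms import displacement_series
    from .vvo_metrics import compute_vvo, out_of_plane

    td = displacement_series(series, mode="TD", radius=radius)
    sts = displacement_series(series, mode="STS", radius=radius)
    vvo = compute_vvo(series, voxel, radius=radius)
    oop = out_of_plane(series, voxel, plane=voxel.plane, radius=radius)
    indicator, _ = censor_regressor(vvo, measure=censor_measure, threshold=censor_threshold)

    data = {
        "volume": np.arange(1, series.n_volumes + 1),
        "td_mm": td.values,
        "sts_mm": sts.values,
    }
    for j, lab in enumerate(LOCATION_LABELS):
        data[f"td_vvo_{lab}"] = vvo.td_vvo[:, j]
    for j, lab in enumerate(LOCATION_LABELS):
        data[f"sts_vvo_{lab}"] = vvo.sts_vvo[:, j]
    data["td_vvo_median"] = vvo.td_vvo_median
    data["sts_vvo_median"] = vvo.sts_vvo_median
    data["out_of_plane_pct"] = oop.values
    data["out_of_plane_defined"] = oop.defined.astype(int)
    data["quality"] = [classify(v, thresholds=thresholds).label for v in vvo.sts_vvo_median]
    data["censored"] = indicator.astype(int)
    per_timepoint = pd.DataFrame(data)

    summary = {
        "td_vvo_median_over_time": float(np.median(vvo.td_vvo_median)),
        "sts_vvo_median_over_time": float(np.median(vvo.sts_vvo_median)),
        "mean_td_mm": float(np.mean(td.values)),
        "mean_sts_mm": float(np.mean(sts.values)),
        "pct_volumes_censored": float(100.0 * indicator.mean()),
        "n_censored": int(indicator.sum()),
    }
    assoc = association_report(vvo, sts, measure="sts_vvo")
    summary["sts_vvo_vs_sts_rho"] = assoc["coefficient"]
    summary["sts_vvo_vs_sts_p"] = assoc["p_value"]
    summary["sts_vvo_vs_sts_defined"] = assoc["defined"]

    meta = {
        "n_volumes": series.n_volumes,
        "voxel_dims_mm": list(voxel.dims),
        "voxel_label": voxel.label,
        "plane": voxel.plane,
        "radius_mm": radius,
        "censor_measure": censor_measure,
        "censor_threshold_pct": censor_threshold,
        "quality_thresholds_pct": list(thresholds),
    }
    if meta_extra:
        meta.update(meta_extra)
    return QCReport(meta=meta, per_timepoint=per_timepoint, summary=summary)
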