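"""Calibration of STS_VVO against conventional STS, and QC outputs.

Because a given scan-to-scan displacement (STS, mm) erodes overlap in
proportion to the voxel size, the two scales are linked per session by
the constrained line ``overlap = 100 - a * STS``: zero movement must
leave 100 % overlap, so the intercept is fixed and only the slope
``a`` (percent overlap lost per mm) is estimated, by least squares
through the origin on the transformed residuals ``100 - overlap``.
Only clinically realistic displacements (0–1.5 mm window) enter the
fit, and a session contributes a slope only if more than 25 % of its
datapoints survive that window.

Default quality cutoffs on STS_VVO are 90 % (very strict), 80 %
(strict), 55 % (lenient) and 35 % (very lenient) — the overlap values
the calibrated line assigns to STS of 0.25, 0.5, 1 and 1.5 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW = (0.0, 1.5)
DEFAULT_MIN_FRACTION = 0.25
DEFAULT_THRESHOLDS = (90.0, 80.0, 55.0)
VERY_LENIENT_MARKER = 35.0

_LABELS = ("very_high", "high", "potentially_acceptable", "questionable")


@dataclass
class CalibrationFit:
    """Result of one session's constrained fit.

    ``a`` is the slope magnitude (percent overlap lost per mm STS);
    it is ``None`` when the session is excluded by the window-survival
    rule or the fit is degenerate (all kept displacements zero).
    """

    a: float | None
    n_total: int
    n_used: int
    included: bool
    window: tuple = DEFAULT_WINDOW

    @property
    def survival_fraction(self) -> float:
        return self.n_used / self.n_total if self.n_total else 0.0


@dataclass
class QualityLabel:
    """Quality category of a timepoint from its STS_VVO value."""

    label: str
    thresholds: tuple = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def fit_constrained(
    sts,
    sts_vvo,
    window=DEFAULT_WINDOW,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> CalibrationFit:
    """Fit ``overlap = 100 - a * STS`` constrained through (0, 100).

    Keeps pairs whose STS lies inside ``window`` (mm, inclusive) and
    solves the regression through the origin
    ``a = sum(x_i (100 - y_i)) / sum(x_i^2)``, the unique least-squares
    slope under the fixed-intercept constraint.  The session is
    ``included`` only if the kept fraction exceeds ``min_fraction``
    and the slope is estimable.
    """
    x = np.asarray(sts, dtype=float)
    y = np.asarray(sts_vvo, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sts and sts_vvo must be 1-D series of equal length")
    if len(x) < 2:
        raise ValueError("need at least two datapoints to fit")
    lo, hi = window
    keep = (x >= lo) & (x <= hi)
    n_total, n_used = len(x), int(keep.sum())
    xk, yk = x[keep], y[keep]
    sxx = float(np.sum(xk**2))
    if n_used / n_total <= min_fraction or sxx == 0.0:
        return CalibrationFit(a=None, n_total=n_total, n_used=n_used, included=False, window=window)
    a = float(np.sum(xk * (100.0 - yk)) / sxx)
    return CalibrationFit(a=abs(a), n_total=n_total, n_used=n_used, included=True, window=window)


def mean_slope(fits) -> float | None:
    """Mean slope over the included sessions; None if none qualify."""
    slopes = [f.a for f in fits if f.included and f.a is not None]
    if not slopes:
        return None
    return float(np.mean(slopes))


def _round_half_away(value: float, ndigits: int = 2) -> float:
    scale = 10**ndigits
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


def lookup_table(a: float, sts_grid=None, step: float = 0.05, window=DEFAULT_WINDOW) -> pd.DataFrame:
    """STS -> STS_VVO correspondence table from a calibrated slope.

    ``STS_VVO = 100 - a * STS``, rounded half-away-from-zero to two
    decimals and clamped below at 0.  The default grid runs 0 to
    1.5 mm in 0.05 mm steps.
    """
    if a < 0:
        raise ValueError("slope a must be non-negative")
    if sts_grid is None:
        lo, hi = window
        n_steps = int(round((hi - lo) / step))
        sts_grid = lo + step * np.arange(n_steps + 1)
    sts_grid = np.asarray(sts_grid, dtype=float)
    vvo = np.maximum(0.0, 100.0 - a * sts_grid)
    vvo = np.array([_round_half_away(v, 2) for v in vvo])
    return pd.DataFrame({"sts_mm": sts_grid, "sts_vvo_pct": vvo})


def classify(sts_vvo: float, thresholds=DEFAULT_THRESHOLDS) -> QualityLabel:
    """Quality label for one STS_VVO percentage.

    Boundaries are inclusive upward: >=90 very_high, >=80 high,
    >=55 potentially_acceptable, below that questionable.
    """
    v = float(sts_vvo)
    if not (0.0 <= v <= 100.0) or not np.isfinite(v):
        raise ValueError(f"STS_VVO must be in [0, 100], got {v}")
    very_high, high, acceptable = thresholds
    if v >= very_high:
        label = "very_high"
    elif v >= high:
        label = "high"
    elif v >= acceptable:
        label = "potentially_acceptable"
    else:
        label = "questionable"
    return QualityLabel(label=label, thresholds=tuple(thresholds))


def censor_regressor(vvo, measure: str = "sts_vvo", threshold: float = 55.0):
    """Censoring ("scrubbing") regressors from a VVO series.

    Flags volumes whose median overlap falls strictly below
    ``threshold`` percent.  Returns ``(indicator, one_hot)`` where
    ``indicator`` is a 0/1 vector over volumes and ``one_hot`` is the
    spike-regressor matrix with one column per flagged volume, ready
    for inclusion in a GLM design.
    """
    if not (0.0 <= threshold <= 100.0):
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    if measure == "sts_vvo":
        values = np.asarray(vvo.sts_vvo_median, dtype=float)
    elif measure == "td_vvo":
        values = np.asarray(vvo.td_vvo_median, dtype=float)
    else:
        raise ValueError(f"measure must be 'sts_vvo' or 'td_vvo', got {measure!r}")
    indicator = (values < threshold).astype(int)
    flagged = np.flatnonzero(indicator)
    one_hot = np.zeros((len(values), len(flagged)))
    for col, t in enumerate(flagged):
        one_hot[t, col] = 1.0
    return indicator, one_hot


def association_report(vvo, disp, measure: str = "sts_vvo", method: str = "spearman") -> dict:
    """Rank correlation between VVO medians and conventional displacement.

    For motion-containing series the association is expected negative
    (more displacement, less overlap).  Constant inputs make the
    coefficient undefined; the report flags this instead of failing.
    """
    if measure == "sts_vvo":
        values = np.asarray(vvo.sts_vvo_median, dtype=float)
    elif measure == "td_vvo":
        values = np.asarray(vvo.td_vvo_median, dtype=float)
    else:
        raise ValueError(f"measure must be 'sts_vvo' or 'td_vvo', got {measure!r}")
    d = np.asarray(disp.values, dtype=float)
    if len(values) != len(d):
        raise ValueError("series lengths differ")
    if len(values) < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    if np.ptp(values) == 0.0 or np.ptp(d) == 0.0:
        return {"method": method, "coefficient": None, "p_value": None, "defined": False}
    if method == "spearman":
        res = stats.spearmanr(d, values)
    elif method == "kendall":
        res = stats.kendalltau(d, values)
    else:
        raise ValueError(f"method must be 'spearman' or 'kendall', got {method!r}")
    coeff = float(res.statistic)
    if not np.isfinite(coeff):
        return {"method": method, "coefficient": None, "p_value": None, "defined": False}
    return {
        "method": method,
        "coefficient": coeff,
        "p_value": float(res.pvalue),
        "defined": True,
    }
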