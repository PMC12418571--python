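"""Synthetic motion-parameter generation for testing and simulation.

Three generators cover the testing needs end to end: ground-truth
single-axis shifts (the validation grid), seeded random walks with
motion spikes (realistic whole-session traces), and paired
STS / STS_VVO samples from a known linear relation (calibration
recovery).  All randomness is driven by explicit seeds and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_motion import MotionSeries

#: the six ground-truth shift magnitudes (mm) of the validation grid
DEFAULT_SHIFT_MAGNITUDES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

_AXIS_IDX = {"x": 0, "y": 1, "z": 2}


@dataclass
class MotionModel:
    """Parameters of the random-walk-plus-spikes trace generator.

    Defaults emulate a typical adult fMRI session: slow drift around
    0.02 mm/volume per axis, occasional (5 %) motion spikes of about
    half a millimetre, and rotations two orders of magnitude smaller
    in radians — landing mean scan-to-scan displacement in the
    0.05–0.3 mm range seen in real cohorts.
    """

    drift_sd: float = 0.02  # mm per volume, per translation axis
    spike_rate: float = 0.05  # probability of a spike per volume
    spike_sd: float = 0.5  # mm, transient spike amplitude
    rot_scale: float = 0.002  # rad per volume, rotation drift
    n_volumes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drift_sd", "spike_rate", "spike_sd", "rot_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike_rate must be a probability")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")


def pure_shift_series(magnitudes=DEFAULT_SHIFT_MAGNITUDES, axis: str = "x") -> MotionSeries:
    """Reference volume followed by one pure single-axis shift per magnitude.

    The ground-truth series of the validation grid: volume 1 is the
    unmoved reference (all zeros); volume k+1 translates by
    ``magnitudes[k]`` mm along ``axis`` with zero rotation.
    """
    if axis not in _AXIS_IDX:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    magnitudes = np.asarray(list(magnitudes), dtype=float)
    if not np.all(np.isfinite(magnitudes)):
        raise ValueError("shift magnitudes must be finite")
    params = np.zeros((len(magnitudes) + 1, 6))
    params[1:, _AXIS_IDX[axis]] = magnitudes
    return MotionSeries(params=params)


def random_series(model: MotionModel, return_spikes: bool = False):
    """Seeded random motion trace: cumulative drift plus transient spikes.

    Translations follow a per-axis Gaussian random walk (sd
    ``drift_sd`` per step); each volume after the first is a spike
    with probability ``spike_rate``, adding a transient (non-
    cumulative) offset of sd ``spike_sd`` mm on all translation axes.
    Rotations follow a random walk of sd ``rot_scale`` rad.  Volume 1
    is all-zero.  With ``return_spikes`` the 0/1 spike indicator is
    returned alongside.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_volumes
    params = np.zeros((n, 6))
    if n > 1:
        steps_t = rng.normal(0.0, model.drift_sd, size=(n - 1, 3))
        steps_r = rng.normal(0.0, model.rot_scale, size=(n - 1, 3))
        params[1:, :3] = np.cumsum(steps_t, axis=0)
        params[1:, 3:] = np.cumsum(steps_r, axis=0)
        spikes = (rng.random(n - 1) < model.spike_rate).astype(int)
        spike_offsets = rng.normal(0.0, model.spike_sd, size=(n - 1, 3))
        params[1:, :3] += spikes[:, None] * spike_offsets
    else:
        spikes = np.zeros(0, dtype=int)
    series = MotionSeries(params=params)
    if return_spikes:
        return series, np.concatenate([[0], spikes])
    return series


def calibration_session(
    a_true: float = 43.2422,
    noise_sd: float = 2.0,
    n: int = 300,
    seed: int = 0,
    sts_scale: float = 0.3,
    window=(0.0, 1.5),
):
    """Paired (STS, STS_VVO) samples from a known linear relation.

    STS is drawn from a half-normal of scale ``sts_scale`` mm
    truncated to ``window`` (rejection sampling); STS_VVO is
    ``100 - a_true * STS`` plus Gaussian noise of sd ``noise_sd``
    percent, clamped to [0, 100].  Used to verify that the constrained
    fit recovers a known generative slope.
    """
    if a_true < 0:
        raise ValueError("a_true must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = window
    sts = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.abs(rng.normal(0.0, sts_scale, size=2 * (n - filled)))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        sts[filled : filled + take] = draw[:take]
        filled += take
    sts_vvo = 100.0 - a_true * sts + rng.normal(0.0, noise_sd, size=n)
    sts_vvo = np.clip(sts_vvo, 0.0, 100.0)
    return sts, sts_vvo
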