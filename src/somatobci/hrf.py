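"""Canonical hemodynamic response model.

The BOLD response to a block of neural activity is modelled as the
convolution of a boxcar (1 during the imagery block, 0 elsewhere) with a
canonical double-gamma impulse response: a positive gamma lobe peaking a few
seconds after stimulus onset followed by a smaller, later undershoot lobe.
The same kernel is used both by the synthetic-data generator and by the
trial-wise GLM, so the feature model is well specified on generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma


@dataclass(frozen=True)
class HrfModel:
    """Double-gamma hemodynamic response function.

    Parameters
    ----------
    peak_delay:
        Time (s) of the positive lobe's maximum. The gamma shape is chosen
        so the mode of the lobe falls exactly at this delay.
    undershoot_delay:
        Time (s) of the undershoot lobe's maximum.
    peak_undershoot_ratio:
        Ratio of peak amplitude to undershoot amplitude (6 means the
        undershoot is one sixth of the peak).
    kernel_length:
        Duration (s) over which the kernel is sampled.
    """

    kind: str = "double-gamma"
    peak_delay: float = 5.0
    undershoot_delay: float = 15.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        if self.kind != "double-gamma":
            raise ValueError(f"unsupported hrf kind: {self.kind!r}")
        if not (0 < self.peak_delay < self.undershoot_delay):
            raise ValueError("require 0 < peak_delay < undershoot_delay")
        if self.peak_undershoot_ratio <= 0:
            raise ValueError("peak_undershoot_ratio must be positive")

    def kernel(self, dt: float) -> np.ndarray:
        """Sample the kernel on ``t = 0, dt, ..., kernel_length``.

        The kernel is zero at t = 0 (a gamma density with shape > 1) and
        normalised to unit peak so regressor amplitudes are comparable
        across hrf parameterisations.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        t = np.arange(0.0, self.kernel_length + dt / 2, dt)
        # gamma mode = (shape - 1) * scale; scale fixed at 1 s
        peak = _gamma.pdf(t, self.peak_delay + 1.0)
        under = _gamma.pdf(t, self.undershoot_delay + 1.0)
        h = peak - under / self.peak_undershoot_ratio
        return h / h.max()


def convolve_boxcar(
    times: np.ndarray,
    onsets: np.ndarray,
    durations: np.ndarray,
    hrf: HrfModel,
    dt: float = 0.1,
) -> np.ndarray:
    """Hrf-convolved boxcar sampled at ``times`` (s).

    The boxcar is 1 on every ``[onset, onset + duration)`` interval and 0
    elsewhere; the convolution is evaluated on a fine grid of step ``dt``
    and linearly interpolated onto the requested sample times. Causality is
    preserved: samples before the first onset are exactly zero.
    """
    times = np.asarray(times, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.asarray(durations, dtype=float), onsets.shape
    )
    if times.size == 0 or onsets.size == 0:
        return np.zeros_like(times)
    t0 = min(times.min(), onsets.min())
    t1 = times.max()
    grid = np.arange(t0, t1 + dt / 2, dt)
    box = np.zeros_like(grid)
    for on, dur in zip(onsets, durations):
        box[(grid >= on) & (grid < on + dur)] = 1.0
    resp = np.convolve(box, hrf.kernel(dt))[: grid.size] * dt
    return np.interp(times, grid, resp)
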