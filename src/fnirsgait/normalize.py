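"""Final band filtering and per-run z-transformation.

The 0.01 Hz high-pass (second order) removes slow drifts; the 0.1 Hz
low-pass (sixth order) removes Mayer waves and residual physiology while
retaining the task frequency.  Both are Butterworth filters applied
zero-phase.  z-scoring (per channel, per run) makes channels averageable
within a region of interest.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import Recording


def band_filter(x: Recording, hp_hz: float = 0.01, hp_order: int = 2,
                lp_hz: float = 0.1, lp_order: int = 6) -> Recording:
    """High-pass then low-pass Butterworth cascade, zero-phase."""
    min_len_s = 2.0 / hp_hz
    if x.duration_s < min_len_s:
        raise ValueError(
            f"record of {x.duration_s:.1f} s shorter than filter warm-up "
            f"({min_len_s:.0f} s needed for the {hp_hz} Hz high-pass)")
    sos_hp = sps.butter(hp_order, hp_hz, btype="high", fs=x.fs_hz, output="sos")
    sos_lp = sps.butter(lp_order, lp_hz, btype="low", fs=x.fs_hz, output="sos")
    data = sps.sosfiltfilt(sos_hp, x.data, axis=1)
    data = sps.sosfiltfilt(sos_lp, data, axis=1)
    return x.copy(data=data)


def zscore_per_run(x: Recording, tol: float = 1e-12) -> Recording:
    """Subtract each channel-run's mean and divide by its sd.

    Zero-variance channels are masked with a warning rather than divided.
    """
    data = x.data.copy()
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = sd[:, 0] <= tol
    newly_masked = set()
    if flat.any():
        for i in np.flatnonzero(flat):
            ch = x.rows["channel"].iloc[i]
            newly_masked.add(ch)
            warnings.warn(f"zero-variance channel {ch} masked, not z-scored")
        sd[flat] = 1.0
    data = (data - mu) / sd
    return x.copy(data=data, unit="zscore", pruned=x.pruned | frozenset(newly_masked))


def butter_gain(fc: float, order: int, f: float, btype: str = "low") -> float:
    """Analytic single-pass Butterworth magnitude at frequency f."""
    if btype == "low":
        return 1.0 / np.sqrt(1.0 + (f / fc) ** (2 * order))
    return 1.0 / np.sqrt(1.0 + (fc / f) ** (2 * order))
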