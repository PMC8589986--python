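"""Shared low-level signal helpers used by the simulator and the detector."""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d


@lru_cache(maxsize=32)
def butter_highpass_sos(order: int, corner_hz: float, sample_rate: float) -> np.ndarray:
    """Second-order sections for a Butterworth high-pass filter.

    Raises ``ValueError`` if the corner frequency is not strictly below
    the Nyquist frequency.  Cached per parameter set.
    """
    nyquist = sample_rate / 2.0
    if not 0 < corner_hz < nyquist:
        raise ValueError(
            f"corner frequency {corner_hz} Hz must lie in (0, {nyquist}) Hz"
        )
    return signal.butter(order, corner_hz, btype="highpass", fs=sample_rate, output="sos")


def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy ``psi[n] = x[n]^2 - x[n-1]*x[n+1]``.

    The two edge samples are copied from their neighbours so the output
    has the same length as the input.  Input dtype is preserved.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    if x.size < 3:
        return np.zeros_like(x)
    psi = np.empty_like(x)
    np.multiply(x[1:-1], x[1:-1], out=psi[1:-1])
    psi[1:-1] -= x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def smoothed_tk_energy(
    x: np.ndarray, sample_rate: float, smooth_s: float = 1e-4
) -> np.ndarray:
    """Teager-Kaiser energy smoothed with a moving average of ``smooth_s``."""
    psi = teager_kaiser(x)
    win = max(1, int(round(smooth_s * sample_rate)))
    if win > 1:
        psi = uniform_filter1d(psi, size=win, mode="nearest")
    return psi
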