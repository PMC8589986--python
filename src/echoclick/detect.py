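"""Transient click detection and peak-frequency detector codes.

The detector high-passes the input, tracks smoothed Teager-Kaiser energy
against a running (chunked-median) noise floor, and keeps energy peaks at
least ``snr_threshold_db`` above the floor, separated by at least one
snippet length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._dsp import butter_highpass_sos, smoothed_tk_energy

__all__ = ["DetectorConfig", "ClickDetection", "highpass", "detect_clicks", "assign_detector_code", "DETECTOR_BINS"]

#: Half-open peak-frequency bins (kHz) -> detector code.
DETECTOR_BINS: tuple[tuple[float, float, int], ...] = (
    (4.0, 20.0, 1),
    (20.0, 50.0, 2),
    (50.0, 70.0, 3),
    (70.0, 100.0, 4),
    (100.0, 150.0, 5),
    (150.0, 250.0, 6),
)


@dataclass(frozen=True)
class DetectorConfig:
    snr_threshold_db: float = 14.0
    highpass_order: int = 4
    highpass_corner_hz: float = 4000.0
    snippet_samples: int = 800
    noise_window_s: float = 5.0
    smooth_s: float = 1e-4

    def __post_init__(self) -> None:
        if self.snr_threshold_db <= 0:
            raise ValueError("snr_threshold_db must be positive")
        if self.snippet_samples < 3:
            raise ValueError("snippet_samples must be >= 3")


@dataclass
class ClickDetection:
    time_s: float
    snr_db: float
    snippet: np.ndarray
    channel: int = 0
    detector_code: int | None = None
    peak_khz: float | None = None
    event_id: str | None = field(default=None)


def highpass(samples: np.ndarray, order: int, corner_hz: float, sample_rate: float) -> np.ndarray:
    """Butterworth high-pass filter (maximally flat, -3 dB at the corner)."""
    sos = butter_highpass_sos(order, corner_hz, sample_rate)
    x = np.asarray(samples)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    return signal.sosfilt(sos, x)


def _chunked_median_floor(energy: np.ndarray, chunk: int, step: int = 4) -> np.ndarray:
    """Noise floor: median of the smoothed energy per noise-window chunk.

    The median is taken over every ``step``-th sample; clicks occupy a
    tiny fraction of any noise window, so the subsampled median is an
    equally robust (and much cheaper) floor estimate.
    """
    n = energy.size
    if chunk >= n:
        return np.full(n, np.median(energy[::step]))
    n_chunks = int(np.ceil(n / chunk))
    floor = np.empty(n)
    for i in range(n_chunks):
        lo, hi = i * chunk, min((i + 1) * chunk, n)
        floor[lo:hi] = np.median(energy[lo:hi:step])
    return floor


def _pick_energy_peaks(ratio: np.ndarray, height: float, distance: int) -> np.ndarray:
    """Greedy peak picker: argmax of each above-threshold run, then
    runs closer than ``distance`` collapse onto the higher peak."""
    idx = np.flatnonzero(ratio >= height)
    if idx.size == 0:
        return idx
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, idx.size - 1]
    peaks = [int(idx[s + np.argmax(ratio[idx[s] : idx[e] + 1])]) for s, e in zip(starts, ends)]
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < distance:
            if ratio[p] > ratio[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept, dtype=int)


def detect_clicks(
    recording: np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    sample_rate: float = 500_000.0,
    time_offset_s: float = 0.0,
    channel: int = 0,
) -> list[ClickDetection]:
    """Detect transient clicks in a sample block.

    Returns detections whose smoothed Teager-Kaiser energy exceeds the
    running noise floor by at least the configured threshold, separated
    by at least one snippet length, each carrying a snippet centred on
    the energy maximum.
    """
    x = np.asarray(recording)
    if x.size == 0:
        return []
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    y = highpass(x, config.highpass_order, config.highpass_corner_hz, sample_rate)
    energy = smoothed_tk_energy(y, sample_rate, config.smooth_s)
    chunk = max(int(round(config.noise_window_s * sample_rate)), config.snippet_samples)
    floor = _chunked_median_floor(energy, chunk)
    floor = np.maximum(floor, np.finfo(np.float32).tiny)
    ratio = energy / floor
    height = 10.0 ** (config.snr_threshold_db / 10.0)
    peaks = _pick_energy_peaks(ratio, height, config.snippet_samples)
    half = config.snippet_samples // 2
    out: list[ClickDetection] = []
    for p in peaks:
        lo = max(p - half, 0)
        hi = min(lo + config.snippet_samples, x.size)
        lo = max(hi - config.snippet_samples, 0)
        snippet = y[lo:hi].copy()
        snr = 10.0 * np.log10(ratio[p])
        out.append(
            ClickDetection(
                time_s=time_offset_s + p / sample_rate,
                snr_db=float(snr),
                snippet=snippet,
                channel=channel,
            )
        )
    return out


def assign_detector_code(peak_khz: float) -> int:
    """Map a click's peak frequency (kHz) onto its detector code.

    Bins are half-open ``[low, high)``; frequencies outside every bin get
    code 0 (unclassified).  Non-positive frequencies are rejected.
    """
    if peak_khz <= 0:
        raise ValueError("peak frequency must be positive")
    for lo, hi, code in DETECTOR_BINS:
        if lo <= peak_khz < hi:
            return code
    return 0
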