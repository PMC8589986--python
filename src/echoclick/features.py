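"""Per-click acoustic parameter extraction.

Twenty parameters per click: three spectral peaks, two troughs, three
peak separations, -3/-10 dB band edges with bandwidth, centre frequency
and Q, Teager-Kaiser duration, and the inter-click interval.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from ._dsp import butter_highpass_sos, teager_kaiser

__all__ = [
    "FEATURE_COLUMNS",
    "STARRED_COLUMNS",
    "SpectrumEstimate",
    "estimate_spectrum",
    "spectral_peaks",
    "band_metrics",
    "click_duration",
    "compute_click_features",
]

#: The 20 per-click parameter column names, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "peak", "peak2", "peak3", "trough", "trough2",
    "peakToPeak2", "peakToPeak3", "peak2ToPeak3",
    "Q_10dB", "Q_3dB",
    "fmin_10dB", "fmin_3dB", "fmax_10dB", "fmax_3dB",
    "BW_10dB", "BW_3dB", "centerHz_10dB", "centerHz_3dB",
    "duration", "ici",
)

#: Subset used for multivariate differentiation (-3 dB versions only).
STARRED_COLUMNS: tuple[str, ...] = (
    "peak", "peak2", "peak3", "trough", "trough2",
    "peakToPeak2", "peakToPeak3", "peak2ToPeak3",
    "Q_3dB", "fmin_3dB", "fmax_3dB", "BW_3dB", "centerHz_3dB",
    "duration", "ici",
)

#: Exclusion half-width (kHz) around already-selected peaks when hunting
#: for the next one, so main-lobe neighbours are not picked as peak2/3.
PEAK_EXCLUSION_KHZ = 2.0


@lru_cache(maxsize=8)
def _hann(n: int) -> np.ndarray:
    return np.hanning(n)


@dataclass
class SpectrumEstimate:
    """dB magnitude spectrum of one click, normalised to 0 dB at its max."""

    freqs_khz: np.ndarray
    db: np.ndarray
    fft_length: int
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.freqs_khz.size != self.db.size:
            raise ValueError("frequency and magnitude arrays differ in length")


def estimate_spectrum(
    snippet: np.ndarray,
    sample_rate: float = 500_000.0,
    fft_length: int = 2048,
    highpass_hz: float = 10_000.0,
    highpass_order: int = 4,
) -> SpectrumEstimate:
    """Magnitude spectrum of the high-passed, Hann-windowed snippet.

    The snippet is zero-padded to ``fft_length`` and the spectrum is
    normalised so its maximum is exactly 0 dB.  All-zero snippets raise.
    """
    x = np.asarray(snippet, dtype=float)
    if x.size == 0:
        raise ValueError("empty snippet")
    if not np.any(x):
        raise ValueError("all-zero snippet has no spectrum")
    if highpass_hz:
        sos = butter_highpass_sos(highpass_order, highpass_hz, sample_rate)
        x = signal.sosfilt(sos, x)
    windowed = x * _hann(x.size)
    mag = np.abs(np.fft.rfft(windowed, n=fft_length))
    mag = np.maximum(mag, np.finfo(float).tiny)
    db = 20.0 * np.log10(mag)
    db -= db.max()
    freqs = np.fft.rfftfreq(fft_length, d=1.0 / sample_rate) / 1000.0
    return SpectrumEstimate(freqs_khz=freqs, db=db, fft_length=fft_length)


def _local_maxima(db: np.ndarray) -> np.ndarray:
    """Indices of local maxima, edges included (compared to one neighbour)."""
    left_ok = np.r_[True, db[1:] >= db[:-1]]
    right_ok = np.r_[db[:-1] >= db[1:], True]
    return np.flatnonzero(left_ok & right_ok)


def _next_peak(
    freqs: np.ndarray, db: np.ndarray, chosen_khz: list[float]
) -> float:
    """Highest local maximum outside the exclusion zones; falls back to
    the highest raw bin outside the zones for unimodal spectra."""
    excluded = np.zeros(freqs.size, dtype=bool)
    for f in chosen_khz:
        excluded |= np.abs(freqs - f) <= PEAK_EXCLUSION_KHZ
    cand = _local_maxima(db)
    cand = cand[~excluded[cand]]
    if cand.size:
        return float(freqs[cand[np.argmax(db[cand])]])
    allowed = np.flatnonzero(~excluded)
    if not allowed.size:
        return float(chosen_khz[-1])
    return float(freqs[allowed[np.argmax(db[allowed])]])


def _trough_between(freqs: np.ndarray, db: np.ndarray, f_a: float, f_b: float) -> float:
    lo, hi = sorted((f_a, f_b))
    mask = (freqs > lo) & (freqs < hi)
    if not mask.any():
        return float(lo)
    sub = np.flatnonzero(mask)
    return float(freqs[sub[np.argmin(db[sub])]])


def spectral_peaks(spectrum: SpectrumEstimate) -> dict[str, float]:
    """peak/peak2/peak3, troughs between them, and peak separations."""
    freqs, db = spectrum.freqs_khz, spectrum.db
    peak = float(freqs[np.argmax(db)])
    peak2 = _next_peak(freqs, db, [peak])
    peak3 = _next_peak(freqs, db, [peak, peak2])
    trough = _trough_between(freqs, db, peak, peak2)
    trough2 = _trough_between(freqs, db, peak2, peak3)
    return {
        "peak": peak,
        "peak2": peak2,
        "peak3": peak3,
        "trough": trough,
        "trough2": trough2,
        "peakToPeak2": abs(peak - peak2),
        "peakToPeak3": abs(peak - peak3),
        "peak2ToPeak3": abs(peak2 - peak3),
    }


def band_metrics(spectrum: SpectrumEstimate, drop_db: float) -> dict[str, float]:
    """Outermost band edges at ``max - drop_db``, linearly interpolated.

    Returns fmin, fmax, bandwidth, centre (``fmin + BW/2``) and Q
    (centre / bandwidth; NaN when the bandwidth is zero).
    """
    freqs, db = spectrum.freqs_khz, spectrum.db
    thr = -float(drop_db)
    above = np.flatnonzero(db >= thr)
    if not above.size:
        raise ValueError("spectrum never reaches the threshold")
    i0, i1 = above[0], above[-1]
    if i0 == 0:
        fmin = float(freqs[0])
    else:
        f_lo, f_hi = freqs[i0 - 1], freqs[i0]
        d_lo, d_hi = db[i0 - 1], db[i0]
        fmin = float(f_lo + (thr - d_lo) * (f_hi - f_lo) / (d_hi - d_lo))
    if i1 == freqs.size - 1:
        fmax = float(freqs[-1])
    else:
        f_lo, f_hi = freqs[i1], freqs[i1 + 1]
        d_lo, d_hi = db[i1], db[i1 + 1]
        fmax = float(f_lo + (thr - d_lo) * (f_hi - f_lo) / (d_hi - d_lo))
    bw = fmax - fmin
    center = fmin + bw / 2.0
    q = center / bw if bw > 0 else float("nan")
    return {"fmin": fmin, "fmax": fmax, "BW": bw, "center": center, "Q": q}


def click_duration(snippet: np.ndarray, sample_rate: float = 500_000.0) -> float:
    """Duration in microseconds: count of samples whose Teager-Kaiser
    energy exceeds 100 times its 40th percentile."""
    x = np.asarray(snippet, dtype=float)
    if x.size < 3:
        return 0.0
    psi = teager_kaiser(x)
    thr = 100.0 * np.percentile(psi, 40)
    count = int(np.count_nonzero(psi > thr))
    return count / sample_rate * 1e6


def compute_click_features(
    snippet: np.ndarray,
    sample_rate: float = 500_000.0,
    click_time_s: float | None = None,
    previous_click_time_s: float | None = None,
    fft_length: int = 2048,
) -> dict[str, float]:
    """Assemble the 20-parameter feature vector for one click.

    ``ici`` is the backward difference to the previous click and is NaN
    for the first click of a train.
    """
    spec = estimate_spectrum(snippet, sample_rate, fft_length=fft_length)
    out = spectral_peaks(spec)
    for drop in (10, 3):
        m = band_metrics(spec, drop)
        out[f"Q_{drop}dB"] = m["Q"]
        out[f"fmin_{drop}dB"] = m["fmin"]
        out[f"fmax_{drop}dB"] = m["fmax"]
        out[f"BW_{drop}dB"] = m["BW"]
        out[f"centerHz_{drop}dB"] = m["center"]
    out["duration"] = click_duration(snippet, sample_rate)
    if click_time_s is not None and previous_click_time_s is not None:
        out["ici"] = click_time_s - previous_click_time_s
    else:
        out["ici"] = float("nan")
    return {k: out[k] for k in FEATURE_COLUMNS}
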