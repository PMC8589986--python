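"""WAV segment readers/writers and ground-truth sidecars.

Recordings are exchanged as 16-bit PCM mono WAV, one file per fixed-length
segment, with filenames encoding encounter and segment index so that a
sorted directory listing reconstructs the gapless timeline.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .simulate import SyntheticDataset, render_recording

__all__ = ["write_wav", "read_wav", "read_recording_set", "export_dataset"]

_PCM16_SCALE = 32767.0


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write float samples in [-1, 1) as 16-bit PCM."""
    clipped = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0 - 1.0 / _PCM16_SCALE)
    wavfile.write(str(path), int(sample_rate), np.round(clipped * _PCM16_SCALE).astype(np.int16))


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a PCM WAV; integer samples are scaled to [-1, 1)."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(float) / _PCM16_SCALE
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483647.0
    else:
        data = data.astype(float)
    return float(rate), data


def read_recording_set(paths: list[str | Path]) -> tuple[np.ndarray, float]:
    """Concatenate WAV segments (in the given order) into one stream.

    All segments must share the sample rate; a rate mismatch or truncated
    file is rejected with the offending file name.
    """
    if not paths:
        raise ValueError("no segment paths given")
    streams = []
    rate0: float | None = None
    n0: int | None = None
    for p in paths:
        try:
            rate, data = read_wav(p)
        except Exception as exc:  # noqa: BLE001 - re-raise with file name
            raise ValueError(f"unreadable WAV segment {p}: {exc}") from exc
        if rate0 is None:
            rate0, n0 = rate, data.size
        elif rate != rate0:
            raise ValueError(f"sample-rate mismatch in {p}: {rate} != {rate0}")
        elif data.size != n0:
            raise ValueError(f"truncated segment {p}: {data.size} != {n0} samples")
        streams.append(data)
    return np.concatenate(streams), rate0


def export_dataset(
    dataset: SyntheticDataset,
    out_dir: str | Path,
    noise_sd: float | None = None,
    which: str = "active",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write WAV segments plus a ground-truth CSV sidecar.

    File names follow ``<encounter>_seg<index>.wav``.  Returns the
    manifest of written segments.  Segment amplitudes are normalised by a
    shared scale so clicks do not clip.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = list(render_recording(dataset, noise_sd=noise_sd, which=which, rng=rng))
    peak = max((np.abs(b).max() for _, _, b in blocks), default=1.0)
    scale = 0.9 / peak if peak > 0 else 1.0
    rows = []
    for enc, si, samples in blocks:
        name = f"{enc}_seg{si:05d}.wav"
        write_wav(out / name, samples * scale, int(dataset.sample_rate))
        rows.append({"encounter": enc, "segment_index": si, "path": name,
                     "start_time_s": si * dataset.segment_length_s})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "segments.csv", index=False)
    dataset.ground_truth().to_csv(out / "ground_truth.csv", index=False)
    return manifest
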