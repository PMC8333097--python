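"""Mono WAV reading/writing on top of scipy.io.wavfile.

Samples are exchanged as float64 in [-1, 1] regardless of the on-disk
encoding (16/32-bit PCM or IEEE float)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav", "peak_normalize"]

_PCM_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a mono WAV file; returns (fs, float64 samples in [-1, 1])."""
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return int(fs), samples


def write_wav(path: str | Path, fs: int, samples: np.ndarray,
              bit_depth: int = 16) -> None:
    """Write float samples in [-1, 1] as PCM (16 or 32 bit)."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    if bit_depth == 16:
        data = np.round(x * (2 ** 15 - 1)).astype(np.int16)
    elif bit_depth == 32:
        data = np.round(x * (2 ** 31 - 1)).astype(np.int32)
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}")
    wavfile.write(str(path), int(fs), data)


def peak_normalize(samples: np.ndarray) -> np.ndarray:
    """Scale so max |x| = 1; all-zero input is returned unchanged."""
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak == 0.0:
        return np.asarray(samples, dtype=np.float64)
    return np.asarray(samples, dtype=np.float64) / peak
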