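"""Learnable sinc-parameterized band-pass filter bank.

A band-pass FIR kernel is the difference of two low-pass sinc kernels,

    g[n; f_l, f_h] = 2 f_h sinc(2 pi f_h n) - 2 f_l sinc(2 pi f_l n),

with ``sinc(x) = sin(x)/x`` (1 at x = 0) and frequencies expressed as
fractions of the sampling rate, so the kernel is dimensionless.  The kernel
is tapered with a Hamming window to reduce spectral ripple.  Each filter of
the bank carries only two learnable parameters, from which the effective
cutoff pair (f_l, f_h) is derived through a continuous, total constraint
mapping; a bank of ``n_filt`` filters therefore has ``2 * n_filt``
parameters regardless of kernel length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "build_kernel",
    "effective_cutoffs",
    "mel_init",
    "filter_bank_convolve",
    "frequency_response",
    "hz_to_mel",
    "mel_to_hz",
    "SincFilterBank",
]


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the removable singularity filled: sinc(0) = 1."""
    # np.sinc is sin(pi t)/(pi t); rescale the argument.
    return np.sinc(x / np.pi)


def hamming_window(length: int) -> np.ndarray:
    """Hamming taper w[m] = 0.54 - 0.46 cos(2 pi m / (I - 1))."""
    m = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * m / (length - 1))


def build_kernel(f_l: float, f_h: float, kernel_len: int, fs: float) -> np.ndarray:
    """Materialize one windowed band-pass sinc kernel.

    Parameters
    ----------
    f_l, f_h
        Low and high cutoff frequencies in Hz; ``0 <= f_l <= f_h <= fs/2``.
        Equal cutoffs yield the all-zero kernel (the band has no width).
    kernel_len
        Odd number of taps, so the kernel is symmetric about a center tap.
    fs
        Sampling frequency in Hz.

    Returns
    -------
    ndarray of shape (kernel_len,), even-symmetric about its center.
    """
    if kernel_len % 2 == 0:
        raise ValueError(f"kernel_len must be odd, got {kernel_len}")
    if f_l < 0 or f_h > fs / 2 or f_l > f_h:
        raise ValueError(
            f"require 0 <= f_l <= f_h <= fs/2, got f_l={f_l}, f_h={f_h}, fs={fs}"
        )
    half = (kernel_len - 1) // 2
    n = np.arange(-half, half + 1, dtype=float)
    fl, fh = f_l / fs, f_h / fs
    g = 2 * fh * _sinc(2 * np.pi * fh * n) - 2 * fl * _sinc(2 * np.pi * fl * n)
    return g * hamming_window(kernel_len)


def effective_cutoffs(
    p_low: np.ndarray, p_band: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained parameters to valid cutoff pairs.

    ``f_l = |p_low|`` and ``f_h = f_l + |p_band|``, both clipped to
    ``[0, fs/2]``.  The mapping is continuous, defined for every real input
    (gradient steps may wander anywhere), and surjective onto the set of
    valid bands, so no constraint can ever be violated during learning.
    """
    p_low = np.asarray(p_low, dtype=float)
    p_band = np.asarray(p_band, dtype=float)
    f_l = np.clip(np.abs(p_low), 0.0, fs / 2)
    f_h = np.clip(f_l + np.abs(p_band), 0.0, fs / 2)
    return f_l, f_h


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_init(n_filt: int, fs: float, f_min: float = 0.0) -> list[tuple[float, float]]:
    """Contiguous cutoff pairs equally spaced on the mel scale.

    ``n_filt + 1`` points span mel(f_min)..mel(fs/2); adjacent points form
    each filter's (f_l, f_h), so band edges are shared and strictly
    increasing.
    """
    if n_filt < 1:
        raise ValueError("n_filt must be >= 1")
    if f_min >= fs / 2:
        raise ValueError(f"f_min={f_min} must be below Nyquist {fs / 2}")
    mels = np.linspace(hz_to_mel(f_min), hz_to_mel(fs / 2), n_filt + 1)
    edges = np.asarray(mel_to_hz(mels), dtype=float)
    edges[0], edges[-1] = f_min, fs / 2  # exact endpoints despite round-trip
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_filt)]


@dataclass
class SincFilterBank:
    """A bank of learnable band-pass sinc filters.

    ``p_low`` and ``p_band`` (Hz) are the raw learnable parameters; the
    effective cutoffs are recovered with :func:`effective_cutoffs`.
    """

    n_filt: int
    kernel_len: int
    fs: float
    p_low: np.ndarray = field(repr=False)
    p_band: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.kernel_len % 2 == 0:
            raise ValueError("kernel_len must be odd")
        self.p_low = np.asarray(self.p_low, dtype=float).copy()
        self.p_band = np.asarray(self.p_band, dtype=float).copy()
        if self.p_low.shape != (self.n_filt,) or self.p_band.shape != (self.n_filt,):
            raise ValueError("p_low/p_band must have shape (n_filt,)")

    @classmethod
    def mel_initialized(
        cls, n_filt: int, kernel_len: int, fs: float, f_min: float = 0.0
    ) -> "SincFilterBank":
        bands = mel_init(n_filt, fs, f_min)
        p_low = np.array([b[0] for b in bands])
        p_band = np.array([b[1] - b[0] for b in bands])
        return cls(n_filt=n_filt, kernel_len=kernel_len, fs=fs,
                   p_low=p_low, p_band=p_band)

    def cutoffs(self) -> tuple[np.ndarray, np.ndarray]:
        return effective_cutoffs(self.p_low, self.p_band, self.fs)

    def kernels(self) -> np.ndarray:
        """Materialize the (n_filt, kernel_len) kernel matrix."""
        f_l, f_h = self.cutoffs()
        return np.stack(
            [build_kernel(lo, hi, self.kernel_len, self.fs)
             for lo, hi in zip(f_l, f_h)]
        )

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_filt": self.n_filt,
            "kernel_len": self.kernel_len,
            "fs": self.fs,
            "p_low": self.p_low.tolist(),
            "p_band": self.p_band.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SincFilterBank":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_filt=payload["n_filt"],
            kernel_len=payload["kernel_len"],
            fs=payload["fs"],
            p_low=np.asarray(payload["p_low"]),
            p_band=np.asarray(payload["p_band"]),
        )


def filter_bank_convolve(samples: np.ndarray, bank: SincFilterBank) -> np.ndarray:
    """Filter a waveform chunk with every kernel of the bank.

    Computed as cross-correlation with the symmetric kernel over the valid
    region (no padding): ``y_j[n] = sum_i x[n + i] k_j[i]``.  Because the
    windowed sinc kernels are even-symmetric this coincides with true
    convolution; the impulse-response test pins the convention.

    Returns an (n_filt, len(samples) - kernel_len + 1) array.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if x.size < bank.kernel_len:
        raise ValueError(
            f"chunk of {x.size} samples is shorter than kernel_len={bank.kernel_len}"
        )
    kernels = bank.kernels()
    windows = np.lib.stride_tricks.sliding_window_view(x, bank.kernel_len)
    return np.ascontiguousarray((windows @ kernels.T).T)


def frequency_response(
    bank: SincFilterBank, n_fft: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time kernels and magnitude spectra for plotting/introspection.

    Returns ``(kernels, freqs_hz, magnitudes)`` where ``kernels`` is
    (n_filt, kernel_len), ``freqs_hz`` the rFFT bin frequencies and
    ``magnitudes`` the (n_filt, n_bins) spectral magnitude of each kernel.
    """
    kernels = bank.kernels()
    if n_fft is None:
        n_fft = max(1024, bank.kernel_len)
    mags = np.abs(np.fft.rfft(kernels, n=n_fft, axis=1))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / bank.fs)
    return kernels, freqs, mags
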