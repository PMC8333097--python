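"""Inspect the learnable sinc band-pass filter bank.

Builds a mel-initialized bank, verifies its band-pass character by locating
each filter's spectral peak, and contrasts its parameter count with an
unconstrained first convolution of the same shape.
"""

import numpy as np

from sincbird import SincFilterBank, build_kernel, frequency_response

fs, n_filt, kernel_len = 16000, 16, 129
bank = SincFilterBank.mel_initialized(n_filt, kernel_len, fs)

kernels, freqs, mags = frequency_response(bank, n_fft=8192)
f_l, f_h = bank.cutoffs()
peaks = freqs[np.argmax(mags, axis=1)]

print(f"{n_filt} filters of {kernel_len} taps at fs={fs} Hz")
print("filter   band (Hz)        spectral peak (Hz)")
for i in (0, 5, 10, 15):
    print(f"{i:>6}   {f_l[i]:7.1f}-{f_h[i]:7.1f}   {peaks[i]:8.1f}")

n_sinc = 2 * n_filt
n_standard = n_filt * kernel_len
print(f"\nlearnable frontend parameters: sinc {n_sinc} "
      f"vs standard conv {n_standard} "
      f"({n_standard / n_sinc:.0f}x fewer with sinc)")

# A single kernel: its center tap equals 2*(f_h - f_l)/fs (both sinc terms
# are 1 at n=0 and the Hamming window is 1 at its center).
k = build_kernel(2000.0, 4000.0, 129, fs)
print(f"center tap of a 2-4 kHz kernel: {k[64]:.6f} "
      f"(expected {2 * 2000 / fs:.6f})")
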