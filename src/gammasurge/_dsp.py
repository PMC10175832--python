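"""Shared zero-phase filtering and analytic-signal helpers."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len


def bandpass(
    x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, ``sosfiltfilt``).

    ``lo <= 0`` degrades to a low-pass, ``hi >= Nyquist`` to a high-pass, so
    band tables that start at 0 Hz (delta) or end at the Nyquist work
    without special-casing at call sites.
    """
    nyq = fs / 2.0
    lo = max(float(lo), 0.0)
    hi = min(float(hi), nyq * 0.999)
    if not lo < hi:
        raise ValueError(f"degenerate band [{lo}, {hi}) at fs={fs}")
    if lo <= 0.0:
        sos = sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    elif hi >= nyq * 0.999:
        sos = sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal via the Hilbert transform, padded to a fast FFT length."""
    n = x.shape[-1]
    nfft = next_fast_len(n)
    return sps.hilbert(x, N=nfft, axis=-1)[..., :n]


def band_limited_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    lo: float,
    hi: float,
    sd: float = 1.0,
    order: int = 4,
) -> np.ndarray:
    """White Gaussian noise filtered to [lo, hi), rescaled to RMS ``sd``."""
    x = bandpass(rng.standard_normal(n), fs, lo, hi, order=order)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= sd / rms
    return x
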