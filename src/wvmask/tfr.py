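"""Analytic signal, discrete Wigner-Ville distribution, and spectrogram.

The Wigner-Ville distribution (WVD) is computed from the analytic signal
x_a = x + jH{x}, which confines the spectrum to (0, fs/2] and removes the
interference between positive- and negative-frequency images.  The
discretization samples the bilinear kernel x_a(t + tau/2) x_a*(t - tau/2)
at half-sample offsets by Fourier-interpolating the analytic signal by a
factor of two, so the lag variable tau advances one full sample per step
and the kernel's Fourier transform over tau is unambiguous across the
whole (0, fs/2] band with no lag-domain folding.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import ShortTimeFFT, hilbert

from .grid import TFRGrid, WindowSpec, default_freqs
from .signals import SampledSignal

__all__ = ["analytic_signal", "wvd", "stft_spectrogram"]


def analytic_signal(signal: SampledSignal) -> SampledSignal:
    """The analytic signal x + jH{x} via the FFT one-sided construction."""
    if signal.is_complex():
        raise ValueError("input is already complex; expected a real signal")
    x = np.asarray(signal.samples, dtype=float)
    # keep the real part bitwise equal to the input; hilbert's FFT round
    # trip would perturb it at machine precision
    return SampledSignal(x + 1j * hilbert(x).imag, fs=signal.fs, t0=signal.t0)


def wvd(signal: SampledSignal, n_freq: int | None = None) -> TFRGrid:
    """Discrete Wigner-Ville distribution on the default grid.

    Parameters
    ----------
    signal : SampledSignal
        Real signal (the analytic transform is applied internally) or an
        already-analytic complex signal.
    n_freq : int, optional
        Number of frequency rows; defaults to the package-wide grid
        (``fs/2`` rows at 1 Hz for whole-second signals).  The maximum
        lag used per column is ``n_freq - 1`` samples.

    Returns
    -------
    TFRGrid
        ``signed_dist`` grid; rows are ``df .. fs/2``.  Values carry the
        lag-step measure ``1/fs`` so that the frequency marginal
        ``sum_f W[f, n] * df`` approximates the instantaneous power
        ``|x_a[n]|**2`` away from the edges.
    """
    if len(signal) < 4:
        raise ValueError("signal too short for a Wigner-Ville distribution")
    if signal.is_complex():
        xa = np.asarray(signal.samples)
    else:
        xa = np.asarray(analytic_signal(signal).samples)
    L = xa.size

    if n_freq is None:
        freqs = default_freqs(signal.fs, L)
    else:
        freqs = (signal.fs / 2 / n_freq) * np.arange(1, n_freq + 1)
    df = freqs[0]
    M = int(round(signal.fs / df))  # lag-FFT length; rows 1..M/2 kept

    # Fourier-interpolate the analytic signal by 2 so the bilinear kernel
    # x_a(t + tau/2) x_a*(t - tau/2) is sampled exactly at integer-sample
    # lag steps tau = u / fs, centered on every original sample instant.
    X = np.fft.fft(xa)
    X2 = np.zeros(2 * L, dtype=complex)
    X2[:L] = X  # analytic: spectrum lives in [0, fs/2]
    x2 = 2.0 * np.fft.ifft(X2)

    kernel = np.zeros((M, L), dtype=complex)
    n = np.arange(L)
    c = 2 * n  # kernel centers on the upsampled axis
    tau_max = np.minimum(np.minimum(c, 2 * L - 1 - c), M // 2 - 1)
    kernel[0] = np.abs(x2[c]) ** 2
    for u in range(1, M // 2):
        cols = tau_max >= u
        idx = c[cols]
        prod = x2[idx + u] * np.conj(x2[idx - u])
        kernel[u, cols] = prod
        kernel[-u, cols] = np.conj(prod)

    spec = np.fft.fft(kernel, axis=0)
    resid = np.max(np.abs(spec.imag)) / max(np.max(np.abs(spec.real)), 1e-300)
    if resid > 1e-8:
        raise AssertionError(f"WVD imaginary residue {resid:.2e} exceeds 1e-8")
    values = spec.real[1 : freqs.size + 1] / signal.fs
    return TFRGrid(values, freqs, signal.times, "signed_dist")


def stft_spectrogram(
    signal: SampledSignal, window: WindowSpec = WindowSpec()
) -> TFRGrid:
    """Spectrogram (squared STFT modulus) on the default grid.

    One column per sample instant (hop of one sample), symmetric
    zero-padding at the edges, Gaussian window per ``window``.
    """
    x = np.asarray(signal.samples, dtype=float)
    L = x.size
    if window.length > L:
        raise ValueError(
            f"window length {window.length} exceeds signal length {L}"
        )
    freqs = default_freqs(signal.fs, L)
    df = freqs[0]
    base = int(round(signal.fs / df))
    # the FFT length must cover the window; oversample the frequency grid
    # by an integer factor and keep every k-th row if needed
    k = max(1, -(-window.length // base))
    stft = ShortTimeFFT(
        window.samples(), hop=1, fs=signal.fs, mfft=k * base, fft_mode="onesided"
    )
    coeff = stft.stft(x, p0=0, p1=L)
    power = np.abs(coeff) ** 2
    # onesided rows are 0..fs/2 at df/k; keep the grid rows, drop f = 0
    return TFRGrid(power[k : k * freqs.size + 1 : k], freqs, signal.times, "power")
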