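"""Synthetic test signals, additive noise, and ECG pre-processing.

The two synthetic signals are the standard multicomponent benchmarks used
throughout the package: signal 1 superposes a linear chirp with a
sinusoidally frequency-modulated high-frequency tone; signal 2 adds and
removes chirp components on a 0.2 s schedule around a constantly present
FM component, producing components that cross and terminate abruptly.
Both default to ``fs = 500`` Hz and 500 samples (1 s of data).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import signal as sps

__all__ = [
    "SampledSignal",
    "NoiseSpec",
    "generate_signal1",
    "generate_signal2",
    "add_awgn",
    "ecg_preprocess",
    "read_signal",
    "write_signal",
]


@dataclasses.dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : ndarray
        Real amplitudes, or complex after the analytic transform.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds. Sample ``n`` sits at
        ``t0 + n / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample instants in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def is_complex(self) -> bool:
        return np.iscomplexobj(self.samples)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a target SNR.

    ``snr_db = inf`` is the "no noise" sentinel.  Noise variance is
    ``mean(signal**2) / 10**(snr_db / 10)`` — total signal power over all
    samples, not a band-limited convention.
    """

    snr_db: float
    seed: int = 0


def _time_axis(fs: float, n_samples: int) -> np.ndarray:
    if not fs > 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if not n_samples >= 2:
        raise ValueError(f"need at least 2 samples, got {n_samples}")
    return np.arange(int(n_samples)) / fs


def generate_signal1(fs: float = 500.0, n_samples: int = 500) -> SampledSignal:
    """Two-component benchmark: linear chirp + sinusoidally FM tone.

    ``x(t) = cos(2pi (20t + 30) t) + cos(2pi (10 sin(2pi t) + 150) t)``

    The first component sweeps upward from 30 Hz (instantaneous frequency
    ``40t + 30``); the second oscillates around 150 Hz.
    """
    t = _time_axis(fs, n_samples)
    x = np.cos(2 * np.pi * (20 * t + 30) * t) + np.cos(
        2 * np.pi * (10 * np.sin(2 * np.pi * t) + 150) * t
    )
    return SampledSignal(x, fs=fs)


# Transient chirps of signal 2: (t_start, t_stop, slope, offset) gives the
# component cos(2*pi*(slope*t + offset)*t) active on the half-open window
# [t_start, t_stop).
_SIGNAL2_SEGMENTS = (
    (0.0, 0.2, 80.0, 120.0),
    (0.0, 0.2, 20.0, 70.0),
    (0.2, 0.4, 80.0, 120.0),
    (0.4, 0.6, -50.0, 120.0),
    (0.6, 0.8, -20.0, 200.0),
    (0.8, 1.0, -20.0, 200.0),
    (0.8, 1.0, 20.0, 70.0),
)


def generate_signal2(fs: float = 500.0, n_samples: int = 500) -> SampledSignal:
    """Multicomponent benchmark with transient, crossing components.

    A constantly present FM component ``cos(2pi (10 sin(2pi t) + 150) t)``
    plus linear chirps switched on and off over five 0.2 s windows
    (half-open, membership decided per sample instant ``t = n / fs``).
    """
    t = _time_axis(fs, n_samples)
    x = np.cos(2 * np.pi * (10 * np.sin(2 * np.pi * t) + 150) * t)
    for t_start, t_stop, slope, offset in _SIGNAL2_SEGMENTS:
        active = (t >= t_start) & (t < t_stop)
        x[active] += np.cos(
            2 * np.pi * (slope * t[active] + offset) * t[active]
        )
    return SampledSignal(x, fs=fs)


def add_awgn(signal: SampledSignal, spec: NoiseSpec) -> SampledSignal:
    """Corrupt a signal with white Gaussian noise at a target SNR.

    Deterministic for a fixed ``spec.seed``.  ``snr_db = inf`` returns the
    signal unchanged.
    """
    if math.isinf(spec.snr_db) and spec.snr_db > 0:
        return signal
    if not math.isfinite(spec.snr_db):
        raise ValueError(f"snr_db must be finite or +inf, got {spec.snr_db}")
    x = np.asarray(signal.samples, dtype=float)
    p_signal = float(np.mean(x**2))
    if p_signal == 0.0:
        raise ValueError("SNR is undefined for an all-zero signal")
    p_noise = p_signal / 10.0 ** (spec.snr_db / 10.0)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(p_noise), size=x.size)
    return SampledSignal(x + noise, fs=signal.fs, t0=signal.t0)


def ecg_preprocess(
    signal: SampledSignal,
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
    notch_q: float = 30.0,
    band: tuple[float, float] = (0.25, 40.0),
    order: int = 4,
) -> SampledSignal:
    """Standard ECG conditioning: power-line notch cascade + bandpass.

    Second-order IIR notches at 60/120/180 Hz (quality factor ``notch_q``)
    remove mains hum and its harmonics; a 4th-order Butterworth bandpass
    (0.25-40 Hz) removes baseline drift and muscle noise.  All filters are
    applied forward-backward so the ECG wave morphology is not skewed by
    phase distortion.  Notches at or above Nyquist are skipped with a
    warning; a bandpass edge at or above Nyquist is an error.
    """
    fs = signal.fs
    nyq = fs / 2.0
    if band[1] >= nyq:
        raise ValueError(
            f"bandpass edge {band[1]} Hz is not below Nyquist ({nyq} Hz)"
        )
    x = np.asarray(signal.samples, dtype=float)
    # generous even-reflection padding: the 0.25 Hz highpass edge and the
    # high-Q notches ring for seconds, far longer than filtfilt's default
    # pad, and odd reflection kicks the sub-hertz band at the boundaries
    padlen = min(x.size - 1, int(5 * fs))
    for f0 in notch_freqs:
        if f0 >= nyq:
            warnings.warn(
                f"skipping {f0} Hz notch: at or above Nyquist ({nyq} Hz)",
                stacklevel=2,
            )
            continue
        b, a = sps.iirnotch(f0, notch_q, fs=fs)
        x = sps.filtfilt(b, a, x, padlen=padlen, padtype="even")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, padlen=padlen, padtype="even")
    return SampledSignal(x, fs=fs, t0=signal.t0)


def write_signal(path, signal: SampledSignal) -> None:
    """Write a signal as two-column (time, amplitude) text with an
    ``# fs=<Hz>`` header comment."""
    header = f"fs={signal.fs:g}\nt0={signal.t0:g}\ntime\tamplitude"
    np.savetxt(
        path,
        np.column_stack([signal.times, signal.samples]),
        header=header,
        delimiter="\t",
    )


def read_signal(path, fs: float | None = None) -> SampledSignal:
    """Read a delimited-text signal.

    Accepts one column (amplitude; ``fs`` required unless in the header) or
    two columns (time, amplitude).  A ``# fs=<Hz>`` header comment takes
    precedence over the time column; an explicit ``fs`` argument overrides
    both.
    """
    header_fs = None
    header_t0 = 0.0
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped.startswith("#"):
                break
            body = stripped.lstrip("#").strip()
            if body.startswith("fs="):
                header_fs = float(body[3:])
            elif body.startswith("t0="):
                header_t0 = float(body[3:])
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 1:
        times, amps = None, data[:, 0]
    else:
        times, amps = data[:, 0], data[:, 1]
    rate = fs if fs is not None else header_fs
    if rate is None:
        if times is None:
            raise ValueError("sampling rate not given and no time column")
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column is not uniformly sampled")
        rate = 1.0 / float(dt[0])
    t0 = float(times[0]) if times is not None else header_t0
    return SampledSignal(amps, fs=float(rate), t0=t0)
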