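"""Dense time-frequency grids shared by all transforms.

Every transform in this package returns a :class:`TFRGrid` on a common
default grid so that distributions from different methods can be combined
elementwise.  For a length-``L`` signal at rate ``fs`` the default grid has
one column per sample instant and frequency rows ``df, 2*df, ..., fs/2``
where ``df = 1`` Hz whenever the signal duration is a whole number of
seconds (the FFT bin spacing ``fs/L`` then divides 1 Hz) and
``df = fs/(2L)`` otherwise.  The zero-frequency row is excluded.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .signals import SampledSignal

__all__ = ["TFRGrid", "WindowSpec", "default_freqs"]

TFRKind = Literal["complex_coeff", "power", "signed_dist"]


def default_freqs(fs: float, n_samples: int) -> np.ndarray:
    """Frequency rows of the default grid: ``df .. fs/2`` inclusive."""
    duration_bins = n_samples / fs  # 1 Hz expressed in fs/L bins
    if abs(duration_bins - round(duration_bins)) < 1e-9 and fs / 2 >= 1.0:
        df = 1.0
    else:
        df = fs / (2 * n_samples)
    n_freq = int(round(fs / 2 / df))
    return df * np.arange(1, n_freq + 1)


@dataclasses.dataclass(frozen=True)
class TFRGrid:
    """A dense time-frequency matrix with explicit axes.

    ``values`` has shape ``(n_freq, n_time)``.  ``kind`` records the
    semantics: ``complex_coeff`` for linear-transform coefficients,
    ``power`` for nonnegative energy densities, ``signed_dist`` for
    real-valued distributions that may go negative (the Wigner-Ville
    distribution).
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    kind: TFRKind

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        freqs = np.asarray(self.freqs, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if values.shape != (freqs.size, times.size):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({freqs.size} freqs, {times.size} times)"
            )
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("frequency axis must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("TFR contains NaN or Inf entries")
        if self.kind == "power":
            if np.iscomplexobj(values) or np.any(values < 0):
                raise ValueError("power TFR must be real and nonnegative")
        elif self.kind == "signed_dist":
            if np.iscomplexobj(values):
                raise ValueError("signed_dist TFR must be real")
        elif self.kind != "complex_coeff":
            raise ValueError(f"unknown TFR kind {self.kind!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "times", times)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 1.0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0

    def axes_match(self, other: "TFRGrid", rtol: float = 1e-9) -> bool:
        return (
            self.freqs.size == other.freqs.size
            and self.times.size == other.times.size
            and np.allclose(self.freqs, other.freqs, rtol=rtol)
            and np.allclose(self.times, other.times, rtol=rtol)
        )

    def magnitude(self) -> "TFRGrid":
        """The elementwise modulus, as a power-kind grid."""
        return TFRGrid(np.abs(self.values), self.freqs, self.times, "power")

    def crop(self, f_lo: float, f_hi: float) -> "TFRGrid":
        """Restrict to frequency rows within ``[f_lo, f_hi]`` (inclusive)."""
        keep = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not np.any(keep):
            raise ValueError(f"no frequency rows in [{f_lo}, {f_hi}] Hz")
        return TFRGrid(self.values[keep], self.freqs[keep], self.times, self.kind)


def default_grid_axes(signal: SampledSignal) -> tuple[np.ndarray, np.ndarray]:
    return default_freqs(signal.fs, len(signal)), signal.times


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """A symmetric analysis window for the short-time Fourier transform.

    ``gaussian_alpha`` follows the usual reciprocal-width convention:
    the standard deviation is ``(length - 1) / (2 * gaussian_alpha)``
    samples, so ``alpha = 2.5`` on a 101-sample window gives a 20-sample
    standard deviation.
    """

    length: int = 101
    shape: str = "gaussian"
    gaussian_alpha: float = 2.5

    def __post_init__(self) -> None:
        if self.length < 3 or self.length % 2 == 0:
            raise ValueError(f"window length must be odd and >= 3, got {self.length}")
        if self.shape != "gaussian":
            raise ValueError(f"unsupported window shape {self.shape!r}")
        if not self.gaussian_alpha > 0:
            raise ValueError("gaussian_alpha must be positive")

    @property
    def std_samples(self) -> float:
        return (self.length - 1) / (2.0 * self.gaussian_alpha)

    def samples(self) -> np.ndarray:
        from scipy.signal import windows

        return windows.gaussian(self.length, std=self.std_samples)
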