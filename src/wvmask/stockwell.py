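"""The S-transform family: original, power-law, IGST, and MST windows.

The S-transform is a linear time-frequency transform using a Gaussian
analysis window whose standard deviation sigma_f varies with the analysed
frequency.  The variants differ only in the sigma_f law:

============  =====================================================
original      sigma_f = 1 / |f|
power_law     sigma_f = |f| ** -r
igst          sigma_f = 1 / (m * |f + p| ** r), with (m, p, r)
              constrained so the window width in samples stays within
              [alpha, beta] over the analysed band
mst           sigma_f = ((f / L_x) + gamma * sigma_x^2) / |f|, driven by
              the input signal's length and amplitude variance
============  =====================================================

The IGST parameters are chosen by maximizing the energy concentration
measure of the resulting transform over a feasible grid (see
:func:`optimize_igst`).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Literal

import numpy as np

from .grid import TFRGrid, default_freqs
from .signals import SampledSignal

__all__ = [
    "STWindowModel",
    "IGSTSearchSpec",
    "sigma_f",
    "check_igst_constraints",
    "s_transform",
    "optimize_igst",
    "mst_model",
    "original_st_model",
]

# Window-width bounds of the IGST feasibility constraints: the Gaussian
# standard deviation, measured in samples, must lie within [ALPHA, BETA]
# across the analysed band [F_MIN, fs/2].
ALPHA = 10.0
BETA = 1000.0
F_MIN = 1.0


@dataclasses.dataclass(frozen=True)
class STWindowModel:
    """The sigma_f law of one S-transform variant."""

    variant: Literal["original", "power_law", "igst", "mst"]
    r_exponent: float = 1.0  # power_law
    m: float = 1.0  # igst
    p: float = 0.0
    r: float = 1.0
    gamma: float = 0.0  # mst
    L_x: int | None = None  # mst signal stats, bound by mst_model
    sigma_x2: float | None = None
    alpha: float = ALPHA
    beta: float = BETA
    f_min: float = F_MIN

    def __post_init__(self) -> None:
        if self.variant == "igst":
            if not (0 < self.m <= 3 and 0 <= self.p <= 3 and 0 <= self.r <= 1):
                raise ValueError(
                    f"IGST parameters out of range: m={self.m}, p={self.p}, "
                    f"r={self.r} (need m in (0,3], p in [0,3], r in [0,1])"
                )
        elif self.variant == "mst" and self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")


def original_st_model() -> STWindowModel:
    return STWindowModel("original")


def sigma_f(model: STWindowModel, f: float | np.ndarray) -> np.ndarray:
    """Gaussian window standard deviation in seconds at frequency f > 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("sigma_f is defined for positive frequencies only")
    if model.variant == "original":
        return 1.0 / np.abs(f)
    if model.variant == "power_law":
        return np.abs(f) ** (-model.r_exponent)
    if model.variant == "igst":
        return 1.0 / (model.m * np.abs(f + model.p) ** model.r)
    if model.variant == "mst":
        if model.L_x is None or model.sigma_x2 is None:
            raise ValueError(
                "MST window requires signal statistics; build it with mst_model()"
            )
        return ((f / model.L_x) + model.gamma * model.sigma_x2) / np.abs(f)
    raise ValueError(f"unknown variant {model.variant!r}")


def check_igst_constraints(
    m: float, p: float, r: float, fs: float
) -> tuple[bool, tuple[float, float]]:
    """Feasibility of an IGST triple at sampling rate fs.

    The window width in samples, sigma_f / T_s, must be at least ``alpha``
    at the top of the band and at most ``beta`` at the bottom:

        alpha * T_s * m * (f_max + p) ** r - 1 <= 0
        1 - beta * T_s * m * (f_min + p) ** r <= 0

    with T_s = 1/fs, f_min = 1 Hz, f_max = fs/2.  Returns the verdict and
    both left-hand-side slack values (feasible iff both are <= 0).
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    ts = 1.0 / fs
    f_max = fs / 2.0
    slack_hi = ALPHA * ts * m * (f_max + p) ** r - 1.0
    slack_lo = 1.0 - BETA * ts * m * (F_MIN + p) ** r
    return (slack_hi <= 0 and slack_lo <= 0), (slack_hi, slack_lo)


def mst_model(signal: SampledSignal, gamma: float) -> STWindowModel:
    """Bind the input-driven MST window to a signal.

    Uses the population variance (divide by L_x) of the time-domain
    amplitudes.  A constant signal degrades gracefully to
    sigma_f = 1 / L_x.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    x = np.asarray(signal.samples, dtype=float)
    return STWindowModel(
        "mst", gamma=gamma, L_x=x.size, sigma_x2=float(np.var(x))
    )


def _gaussian_voice_filters(
    freqs: np.ndarray, sigmas: np.ndarray, L: int, fs: float
) -> np.ndarray:
    """Frequency response of each row's Gaussian window, sampled on the
    length-L FFT grid (centered bins)."""
    nu = np.fft.fftfreq(L, d=1.0 / fs)  # Hz offsets from the voice frequency
    return np.exp(-2.0 * np.pi**2 * sigmas[:, None] ** 2 * nu[None, :] ** 2)


def s_transform(
    signal: SampledSignal,
    model: STWindowModel,
    freqs: np.ndarray | None = None,
    enforce_constraints: bool = True,
) -> TFRGrid:
    """S-transform on the default grid via the spectral voice algorithm.

    For each frequency row f the demodulated spectrum X(nu + f) is
    multiplied by the Fourier transform exp(-2 pi^2 sigma_f^2 nu^2) of the
    unit-area Gaussian window and inverse-transformed over time.  This is
    exactly the circular discretization of the integral definition with a
    periodized window, and a pure cosine yields a coefficient modulus of
    1/2 at its own frequency.
    """
    if signal.is_complex():
        raise ValueError("expected a real input signal")
    if model.variant == "igst" and enforce_constraints:
        ok, slacks = check_igst_constraints(model.m, model.p, model.r, signal.fs)
        if not ok:
            raise ValueError(
                f"IGST parameters (m={model.m}, p={model.p}, r={model.r}) "
                f"violate the window-width constraints (slacks {slacks})"
            )
    if model.variant == "mst" and model.L_x is None:
        model = mst_model(signal, model.gamma)

    x = np.asarray(signal.samples, dtype=float)
    L = x.size
    if freqs is None:
        freqs = default_freqs(signal.fs, L)
    sigmas = sigma_f(model, freqs)
    H = _gaussian_voice_filters(freqs, sigmas, L, signal.fs)

    X = np.fft.fft(x) / L
    bin_hz = signal.fs / L
    shifts = freqs / bin_hz
    shifted = np.empty((freqs.size, L), dtype=complex)
    int_shifts = np.rint(shifts)
    if np.allclose(shifts, int_shifts, atol=1e-9):
        for i, s in enumerate(int_shifts.astype(int)):
            shifted[i] = np.roll(X, -s)
    else:
        # grid frequencies off the FFT bins: demodulate per row
        n = np.arange(L)
        for i, f in enumerate(freqs):
            shifted[i] = np.fft.fft(x * np.exp(-2j * np.pi * f * n / signal.fs)) / L
    values = np.fft.ifft(shifted * H, axis=1) * L
    return TFRGrid(values, np.asarray(freqs, float), signal.times, "complex_coeff")


@dataclasses.dataclass(frozen=True)
class IGSTSearchSpec:
    """Inclusive parameter grids for the IGST concentration search."""

    m_range: tuple[float, float] = (0.05, 3.0)
    p_range: tuple[float, float] = (0.0, 3.0)
    r_range: tuple[float, float] = (0.0, 1.0)
    step: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.m_range[0] and self.m_range[1] <= 3):
            raise ValueError("m grid must lie within (0, 3]")
        if not (0 <= self.p_range[0] and self.p_range[1] <= 3):
            raise ValueError("p grid must lie within [0, 3]")
        if not (0 <= self.r_range[0] and self.r_range[1] <= 1):
            raise ValueError("r grid must lie within [0, 1]")
        if not self.step > 0:
            raise ValueError("step must be positive")

    def axis(self, lo: float, hi: float) -> np.ndarray:
        n = int(np.floor((hi - lo) / self.step + 1e-9)) + 1
        return lo + self.step * np.arange(n)

    def triples(self):
        return itertools.product(
            self.axis(*self.m_range),
            self.axis(*self.p_range),
            self.axis(*self.r_range),
        )


def optimize_igst(
    signal: SampledSignal,
    spec: IGSTSearchSpec = IGSTSearchSpec(),
    cm_mode: str = "rms",
) -> tuple[STWindowModel, float]:
    """Exhaustive feasible-grid search for the CM-maximizing IGST window.

    Evaluates the concentration measure of |ST| for every feasible
    (m, p, r) triple on the grids and returns the winner with its CM.
    Ties break toward the lexicographically smallest triple; the search is
    deterministic.  Raises if no grid point is feasible.
    """
    from .metrics import concentration_measure

    x = np.asarray(signal.samples, dtype=float)
    L = x.size
    freqs = default_freqs(signal.fs, L)
    bin_hz = signal.fs / L
    shifts = np.rint(freqs / bin_hz).astype(int)
    X = np.fft.fft(x) / L
    if np.allclose(freqs / bin_hz, shifts, atol=1e-9):
        shifted = np.stack([np.roll(X, -s) for s in shifts])
    else:
        n = np.arange(L)
        shifted = np.stack(
            [np.fft.fft(x * np.exp(-2j * np.pi * f * n / signal.fs)) / L for f in freqs]
        )

    best: tuple[float, tuple[float, float, float]] | None = None
    for m, p, r in spec.triples():
        ok, _ = check_igst_constraints(m, p, r, signal.fs)
        if not ok:
            continue
        sig = 1.0 / (m * np.abs(freqs + p) ** r)
        H = _gaussian_voice_filters(freqs, sig, L, signal.fs)
        values = np.fft.ifft(shifted * H, axis=1) * L
        grid = TFRGrid(np.abs(values), freqs, signal.times, "power")
        cm = concentration_measure(grid, mode=cm_mode)
        key = (-cm, (m, p, r))
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no feasible IGST parameter triple on the given grids")
    cm_best, (m, p, r) = -best[0], best[1]
    return STWindowModel("igst", m=float(m), p=float(p), r=float(r)), cm_best
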