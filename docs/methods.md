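# Methods

This note records the models, discretizations and conventions behind
`wvmask`, the defaults and why they were chosen, and what the test suite
does and does not establish.

## Signals

Two synthetic benchmarks define the reference configuration: 500 samples
at fs = 500 Hz (1 s), so the default time-frequency grid is 250 frequency
rows (1…250 Hz at 1 Hz) × 500 time columns.

* **Signal 1** — cos(2π(20t+30)t) + cos(2π(10 sin(2πt)+150)t): a linear
  chirp whose instantaneous frequency rises 30 → 70 Hz, plus a
  sinusoidally FM tone oscillating around 150 Hz.
* **Signal 2** — a constantly present FM component around 150 Hz plus
  linear chirps switched on and off over five half-open 0.2 s windows,
  so components appear, vanish and cross. Segment membership is decided
  per sample instant t = n/fs.

Additive white Gaussian noise is specified by a target SNR in dB with
the total-power convention: noise variance = mean(x²)/10^(SNR/10),
i.i.d. per sample, deterministic for a given seed (`NoiseSpec`).
`snr_db = inf` means "no noise". The noisy tables in the literature this
package benchmarks against are single realizations, so noisy values are
treated as stochastic reference points (trends, not digits).

## Time-frequency grid

All transforms return a `TFRGrid` on a common grid: one column per
sample instant; frequency rows Δf…fs/2 with Δf = 1 Hz when the signal
duration is a whole number of seconds, else Δf = fs/(2L). The zero
frequency row is excluded (the analysis band starts at f_min = 1 Hz).
Shared axes are what make elementwise masking well-defined; this is
asserted, not assumed.

## Discrete WVD

The WVD is computed from the analytic signal (FFT one-sided
construction; the real part is kept bitwise equal to the input). The
bilinear kernel x_a(t+τ/2)x_a*(t−τ/2) needs values midway between
samples, so the analytic signal is Fourier-interpolated by a factor of
two and the kernel r_n[u] = x2[2n+u]·x2*[2n−u] is formed over the
maximal symmetric lag range (capped at fs/(2Δf)−1 lags), then
Fourier-transformed over the lag. Because the analytic spectrum lives in
[0, fs/2], the transform is unambiguous over the full band with no
lag-domain aliasing. Values carry the lag measure 1/fs, so the frequency
marginal Σ_f W·Δf reproduces the instantaneous power |x_a(t)|² away from
the edges — exactly for a pure tone, and this is tested.

This half-sample-lag form was chosen over the integer-lag folded
variant: both give the textbook tone-line and marginal properties, but
the interpolated kernel reproduces the reference concentration tables
noticeably better (≤0.5% on CM, ≤0.02 bits on RE across all 18 clean
entries, versus ~2%/0.04 bits for the folded form), indicating it
matches the discretization used to produce them.

## Spectrogram

`ShortTimeFFT` with hop 1 (a column per sample), symmetric zero padding,
and a Gaussian window specified by an odd length and the reciprocal
width α, std = (length−1)/(2α) samples. The reference configuration is
length 101 with α = 2.5 (std 20 samples); α is the main free knob and is
exposed. If the grid would need an FFT shorter than the window, the
frequency axis is oversampled by an integer factor and decimated back.

## S-transform

Each frequency row is computed by the spectral "voice" algorithm: shift
the signal spectrum by f, multiply by the Gaussian's transform
e^{−2π²σ_f²ν²}, inverse-FFT over time. This is exactly the circular
discretization of the defining integral with a periodized unit-area
window — the test suite pins it against direct quadrature at 1e-6 — and
a real cosine yields a coefficient modulus of 1/2 at its own frequency.
Frequencies that fall on FFT bins use an index roll; off-bin rows fall
back to per-row demodulation.

Window-law specifics:

* **IGST** constraints are read as α·T_s·m·(f_max+p)^r − 1 ≤ 0 and
  1 − β·T_s·m·(f_min+p)^r ≤ 0 with α = 10, β = 1000, f_min = 1 Hz,
  f_max = fs/2: the window width in samples must stay within
  [α, β] across the analysed band. This is the only reading under which
  both constants are meaningful, and the reference optima
  (m, p, r) = (1.0452, 0.9908, 0.6956), (1.0314, 0.9910, 0.6900),
  (1.0063, 0.9914, 0.6979) are all feasible at fs = 500 (verified).
  Note the original ST window 1/f itself violates the upper constraint
  at fs = 500 — that is the point of the generalization.
* **IGST search**: exhaustive grid over feasible (m, p, r), maximizing
  the concentration measure of |ST|; deterministic, ties broken toward
  the lexicographically smallest triple. The default step is 0.05 per
  axis, a compromise between fidelity to the 4-decimal reference optima
  (which imply a finer or locally refined search) and the cost of an
  exhaustive scan; the step is a parameter, and tests use coarser grids
  sized to their runtime.
* **MST**: σ_f = (f/L_x + γσ_x²)/|f| = 1/L_x + γσ_x²/|f| with L_x the
  signal length and σ_x² the population variance of the time-domain
  amplitudes. γ is signal-dependent (4 for the synthetic benchmarks;
  much smaller for spiky large-dynamic-range signals such as ECG). A
  constant signal degrades gracefully to σ_f = 1/L_x.

## Masking and metrics conventions

Masked WVD = |WVD| ⊙ mask, where the mask is the linear transform's
modulus raised to `mask_exponent`. Two conventions are defensible:
exponent 2 (the literal spectrogram) and exponent 1 (plain magnitude).
**The package default is exponent 1**, uniformly for STFT and STs: the
reference comparison tables are reproduced to four significant figures
by magnitude masks (e.g. clean signal 1 STFT mask: CM 6.5214 vs 6.5213
reference; RE 14.3507 vs 14.3507), while squared masks are ~30% off. So
although masking is usually described in terms of the spectrogram, the
numbers behave as |STFT|. The exponent remains configurable.

Concentration measure: CM = 1/ΣΣ|V̄| with V̄ the modulus normalized by
the square root of the energy (`rms` mode) and unit (index) cell
measure, making CM scale-invariant — 1 for a single occupied cell,
1/√N for a uniform TFR over N cells (≈2.83×10⁻³ on the 250×500 grid,
the scale of the reference tables). The literal energy-normalized form
(`as_printed`, divide by E rather than √E) is scale-dependent; it is
implemented, tested, and selectable, but the reference values are only
reproduced by the rms/index convention, which is therefore the default
and is recorded in every `MetricsReport` / table header.

Rényi entropy: RE = (1−ε)^{−1} log₂ ΣΣ p^ε with p the unit-sum TFR
modulus, default ε = 3. Scale- and cell-invariant; bounded by
log₂(n_cells) ≈ 16.93 on the reference grid.

Noisy-case evaluations keep the IGST window fixed at the clean-signal
optimum rather than re-optimizing per realization: the SNR-trend claims
do not depend on re-optimization and an exhaustive search per seed would
dominate runtime.

## ECG pre-processing

Second-order IIR notches at 60/120/180 Hz (Q = 30) and a 4th-order
Butterworth bandpass 0.25–40 Hz, all applied forward-backward for zero
phase. Filters use even-reflection padding of up to 5 s: the sub-hertz
highpass edge rings for seconds, and odd reflection would inject a
boundary transient into exactly the band the filter is meant to pass.
Notches at or above Nyquist are skipped with a warning; a bandpass edge
at or above Nyquist is an error. The chain is linear and
length-preserving (tested), and achieves ≥20 dB at 60 Hz, ≤1 dB ripple
at 10 Hz and ≥40 dB DC rejection at fs = 600 Hz.

## What the synthetic benchmarks do and do not show

The generators emulate multicomponent non-stationarity: crossing,
appearing/vanishing and FM components, plus white noise at controlled
SNR. They do not emulate physiological variability, impulsive artifacts,
colored noise, or sub-hertz baseline wander, so passing the benchmark
suite shows correctness of the transforms and metrics and the masking
mechanism — not clinical adequacy on real ECG. The ECG path is exercised
with synthetic tones only; real records (e.g. MIT-BIH format via `wfdb`)
can be fed through `read_signal`/`ecg_preprocess` but are not required
by any test.

## Problem sizes and determinism

All quantitative checks run on the reference configuration (500-sample
signals, 250×500 grids); small-instance oracles use L = 64. The noisy
trend suite uses 5 seeds per SNR at 15/10/5 dB and compares means across
seeds. Everything is deterministic given seeds; clean-signal numbers are
exactly reproducible.

## Known limitations

* No pseudo/smoothed-pseudo WVD, Cohen-class kernels, reassignment or
  synchrosqueezing; no EMD/VMD decomposition-based cross-term reduction.
* The IGST grid search is exhaustive, not refined; reported optima are
  grid-resolution approximations of the 4-decimal reference triples.
* `as_printed` CM values depend on the TFR's absolute scale and are not
  comparable across transforms with different normalizations; use `rms`
  for cross-method comparisons.
* The text TFR format stores real grids only (write the modulus of a
  complex transform, or use the `.npz` container).
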