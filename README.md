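# wvmask — masked Wigner-Ville distributions

Cross-term suppression for time-frequency analysis of non-stationary
signals, aimed at biomedical signal processing (multicomponent synthetic
benchmarks, ECG), with the concentration metrics used to compare
time-frequency representations (TFRs).

## The problem and the method

The Wigner-Ville distribution (WVD) of the analytic signal
x_a(t) = x(t) + jH{x(t)},

    W_x(t, f) = ∫ x_a(t + τ/2) x_a*(t − τ/2) e^{−j2πfτ} dτ,

has the sharpest resolution of any standard TFR, but its bilinear form
creates oscillatory *cross-terms* midway between every pair of true
components. Linear transforms — the STFT and the S-transform (ST) family —
are cross-term free but blurrier. A **masked WVD** takes the best of both:
multiply the WVD elementwise by a cross-term-free TFR of the same signal,
so the WVD's sharp auto-terms survive where the linear method also sees
energy and the interference regions are driven toward zero.

The masking TFRs implemented are the Gaussian-window STFT and the
S-transform

    ST_x(t, f) = ∫ x(τ) w(τ − t, σ_f) e^{−j2πfτ} dτ,
    w(t, σ_f) = (2π)^{−1/2} σ_f^{−1} e^{−t²/2σ_f²},

in four window-width laws:

| variant    | σ_f                              | notes |
|------------|----------------------------------|-------|
| original   | 1 / \|f\|                        | classic Stockwell window |
| power-law  | \|f\|^−r                         | tunable decay |
| IGST       | 1 / (m·\|f + p\|^r)              | (m, p, r) found by maximizing concentration, constrained so the window stays 10–1000 samples wide over [1 Hz, fs/2] |
| MST        | (f/L_x + γσ_x²) / \|f\|          | input-driven: uses the signal length L_x and amplitude variance σ_x² |

Concentration is scored two ways: the energy concentration measure
CM = 1 / ΣΣ|TFR̄| with the TFR normalized to unit energy (higher = more
concentrated) and the order-ε Rényi entropy
RE = (1 − ε)^{−1} log₂ ΣΣ p^ε of the unit-sum TFR modulus at ε = 3
(lower = more concentrated).

An ECG pre-conditioning chain (60/120/180 Hz notches + 0.25–40 Hz
zero-phase Butterworth bandpass) is included for applying the pipeline to
physiological records.

## Worked example

```python
from wvmask import STWindowModel, generate_signal1
from wvmask.masking import evaluate_pipeline

igst = STWindowModel("igst", m=1.0452, p=0.9908, r=0.6956)
table = evaluate_pipeline(generate_signal1(), igst_model=igst)
print(table)
```

`generate_signal1()` builds the 1 s, 500 Hz benchmark
cos(2π(20t+30)t) + cos(2π(10 sin(2πt)+150)t) — a linear chirp plus a
sinusoidally frequency-modulated tone. Running
`python examples/concentration_table.py` prints:

```
TFR               CM x10^-3  RE (bits)
WVD                  6.0604    14.3094
mask (stft)          6.5214    14.3507
masked (stft)       13.3639    11.9520
mask (st)            4.0552    15.7824
masked (st)          8.6072    13.1949
mask (igst)          6.5490    14.3571
masked (igst)       12.8467    12.1299
mask (mst)           6.4802    14.3775
masked (mst)        12.4272    12.2595
```

Every masked WVD beats the raw WVD on both metrics (CM roughly doubles,
RE drops by ~2 bits), and the original ST — whose fixed 1/f window is too
narrow at high frequencies — is the weakest mask on both. The other
examples demonstrate cross-term band suppression on a two-tone signal
(99% of the relative interference energy removed), the window laws and
the IGST feasibility search, and the ECG filter chain (−39 dB at 60 Hz,
0 dB at 10 Hz).

A thin CLI mirrors the library:

```sh
wvmask generate --signal signal1 -o s1.tsv
wvmask evaluate --signal signal1 --igst 1.0452,0.9908,0.6956 -o table.tsv
wvmask reproduce-tables --out-dir tables/
```

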