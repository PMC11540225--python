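"""S-transform family: window laws, constraints, transform, optimization."""

import numpy as np
import pytest

import wvmask as wm
from wvmask.signals import SampledSignal
from wvmask.stockwell import (
    ALPHA,
    BETA,
    IGSTSearchSpec,
    STWindowModel,
    check_igst_constraints,
    mst_model,
    s_transform,
    sigma_f,
)

# Concentration-search optima for the clean benchmark signals at fs=500,
# plus the 15 dB noisy-case optima; all must satisfy the width constraints.
REFERENCE_TRIPLES = [
    (1.0452, 0.9908, 0.6956),
    (1.0314, 0.9910, 0.6900),
    (1.0063, 0.9914, 0.6979),
]


class TestSigmaF:
    def test_original_is_reciprocal_frequency(self):
        assert sigma_f(STWindowModel("original"), 10.0) == pytest.approx(0.1)

    def test_igst_with_unit_parameters_reduces_to_original(self):
        igst = STWindowModel("igst", m=1.0, p=0.0, r=1.0)
        f = np.array([1.0, 7.0, 150.0])
        np.testing.assert_allclose(
            sigma_f(igst, f), sigma_f(STWindowModel("original"), f)
        )

    def test_igst_reference_parameters_scalar_evaluation(self):
        m, p, r = REFERENCE_TRIPLES[0]
        model = STWindowModel("igst", m=m, p=p, r=r)
        expected = 1.0 / (m * (250.0 + p) ** r)
        assert sigma_f(model, 250.0) == pytest.approx(expected, rel=1e-12)

    def test_power_law(self):
        model = STWindowModel("power_law", r_exponent=0.8)
        assert sigma_f(model, 16.0) == pytest.approx(16.0**-0.8)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            sigma_f(STWindowModel("original"), 0.0)

    def test_mst_requires_signal_stats(self):
        with pytest.raises(ValueError):
            sigma_f(STWindowModel("mst", gamma=1.0), 10.0)

    def test_igst_parameter_ranges_enforced(self):
        with pytest.raises(ValueError):
            STWindowModel("igst", m=3.5, p=0.0, r=0.5)
        with pytest.raises(ValueError):
            STWindowModel("igst", m=1.0, p=-0.1, r=0.5)


class TestIGSTConstraints:
    @pytest.mark.parametrize("triple", REFERENCE_TRIPLES)
    def test_reference_triples_feasible(self, triple):
        ok, (hi, lo) = check_igst_constraints(*triple, fs=500.0)
        assert ok and hi <= 0 and lo <= 0

    def test_first_reference_triple_slack_values(self):
        # independent scalar evaluation of both constraint left-hand sides
        m, p, r = REFERENCE_TRIPLES[0]
        _, (hi, lo) = check_igst_constraints(m, p, r, fs=500.0)
        assert hi == pytest.approx(10 * 0.002 * m * (250 + p) ** r - 1, rel=1e-12)
        assert hi == pytest.approx(-0.024, abs=0.002)
        assert lo == pytest.approx(-2.37, abs=0.01)

    def test_upper_corner_infeasible(self):
        # window narrower than alpha samples at f_max
        ok, (hi, _) = check_igst_constraints(3.0, 3.0, 1.0, fs=500.0)
        assert not ok and hi > 0

    def test_vanishing_m_infeasible(self):
        # window wider than beta samples at f_min
        ok, (_, lo) = check_igst_constraints(1e-6, 1.0, 0.5, fs=500.0)
        assert not ok and lo > 0


def _quadrature_st(x, fs, f, sigma):
    """Direct discrete quadrature of the S-transform integral with a
    periodized unit-area Gaussian window (independent oracle)."""
    L = x.size
    ts = 1.0 / fs
    T = L * ts
    n = np.arange(L)
    out = np.empty(L, dtype=complex)
    phase = np.exp(-2j * np.pi * f * n * ts)
    for i in range(L):
        tau = (n - i) * ts
        w = np.zeros(L)
        for k in range(-4, 5):
            w += np.exp(-((tau + k * T) ** 2) / (2 * sigma**2))
        w /= np.sqrt(2 * np.pi) * sigma
        out[i] = np.sum(x * w * phase) * ts
    return out


class TestSTransform:
    def test_zero_signal(self):
        st = s_transform(SampledSignal(np.zeros(64), fs=64.0), STWindowModel("original"))
        assert np.all(st.values == 0)

    def test_tone_coefficient_is_half(self, tone):
        st = s_transform(tone(100.0), STWindowModel("original"))
        row = np.abs(st.values[np.searchsorted(st.freqs, 100.0)])
        ridge = st.freqs[np.argmax(np.abs(st.values[:, 100:400]), axis=0)]
        assert np.all(ridge == 100.0)
        np.testing.assert_allclose(row[100:400], 0.5, rtol=0.05)

    @pytest.mark.parametrize("freq", [5.0, 13.0, 27.0])
    def test_matches_direct_quadrature(self, freq):
        # the module's core oracle: spectral voice algorithm vs direct
        # integral evaluation on a small instance
        rng = np.random.default_rng(3)
        fs, L = 64.0, 64
        x = rng.normal(size=L)
        model = STWindowModel("original")
        st = s_transform(SampledSignal(x, fs=fs), model)
        row = st.values[np.searchsorted(st.freqs, freq)]
        oracle = _quadrature_st(x, fs, freq, float(sigma_f(model, freq)))
        np.testing.assert_allclose(
            row, oracle, atol=1e-6 * np.max(np.abs(oracle))
        )

    def test_gaussian_window_has_unit_area(self, signal1):
        # discrete sum x dt of the effective window for sigma spanning >= 3
        # samples stays within 1e-3 of one
        fs, L = signal1.fs, len(signal1)
        ts = 1.0 / fs
        for sigma in (3 * ts, 10 * ts, 0.05, 0.1):
            tau = (np.arange(L) - L // 2) * ts
            w = np.exp(-(tau**2) / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
            assert np.sum(w) * ts == pytest.approx(1.0, abs=1e-3)

    def test_wide_window_limit_is_fourier_coefficient(self, signal1):
        # sigma_f -> infinity: the window flattens and each row tends to the
        # plain Fourier coefficient of the signal
        x = np.asarray(signal1.samples)
        L = x.size
        st = s_transform(
            signal1, STWindowModel("power_law", r_exponent=-2.0)
        )  # sigma_f = f^2: huge at high rows
        k = 240
        fourier = np.fft.fft(x)[k] / L
        row = st.values[np.searchsorted(st.freqs, float(k))]
        np.testing.assert_allclose(row, fourier, rtol=0.01)

    def test_infeasible_igst_rejected(self, signal1):
        bad = STWindowModel("igst", m=3.0, p=3.0, r=1.0)
        with pytest.raises(ValueError):
            s_transform(signal1, bad)

    def test_complex_input_rejected(self):
        sig = SampledSignal(np.ones(16, dtype=complex), fs=16.0)
        with pytest.raises(ValueError):
            s_transform(sig, STWindowModel("original"))


class TestMSTModel:
    def test_binds_length_and_population_variance(self, signal1):
        model = mst_model(signal1, gamma=4.0)
        assert model.L_x == 500
        assert model.sigma_x2 == pytest.approx(np.var(signal1.samples))

    def test_gamma_zero_gives_reciprocal_length(self):
        rng = np.random.default_rng(0)
        sig = SampledSignal(rng.normal(size=100), fs=100.0)
        model = mst_model(sig, gamma=0.0)
        f = np.array([1.0, 10.0, 50.0])
        np.testing.assert_allclose(sigma_f(model, f), 1.0 / 100.0)

    def test_constant_signal_degrades_gracefully(self):
        sig = SampledSignal(np.full(64, 2.5), fs=64.0)
        model = mst_model(sig, gamma=3.0)
        assert sigma_f(model, 8.0) == pytest.approx(1.0 / 64.0)

    def test_extreme_amplitudes_small_gamma_finite(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=360) * 1e3
        x[::60] = 5e4  # spiky, ECG-like dynamic range
        sig = SampledSignal(x, fs=360.0)
        model = mst_model(sig, gamma=2.5e-4)
        vals = sigma_f(model, np.arange(1.0, 181.0))
        assert np.all(np.isfinite(vals)) and np.all(vals > 0)

    def test_negative_gamma_rejected(self, signal1):
        with pytest.raises(ValueError):
            mst_model(signal1, gamma=-0.1)


class TestOptimizeIGST:
    def test_singleton_grid_returns_that_triple(self, signal1):
        # (1, 1, 0.7) is feasible at fs=500; a singleton search must
        # return exactly that triple
        spec = IGSTSearchSpec(
            m_range=(1.0, 1.0), p_range=(1.0, 1.0), r_range=(0.7, 0.7), step=1.0
        )
        model, cm = wm.optimize_igst(signal1, spec)
        assert (model.m, model.p, model.r) == (1.0, 1.0, 0.7)
        assert cm > 0

    def test_original_st_window_itself_is_infeasible(self):
        # sigma_f = 1/f is only 2 samples wide at f_max: the width
        # constraints exist precisely to exclude it
        ok, (hi, _) = check_igst_constraints(1.0, 0.0, 1.0, fs=500.0)
        assert not ok and hi > 0

    def test_argmax_dominates_fixed_feasible_point(self, signal1):
        from wvmask.metrics import concentration_measure

        spec = IGSTSearchSpec(step=0.5)
        model, cm = wm.optimize_igst(signal1, spec)
        ok, _ = check_igst_constraints(model.m, model.p, model.r, signal1.fs)
        assert ok
        st = s_transform(signal1, STWindowModel("original"))
        cm_original = concentration_measure(st.magnitude())
        assert cm >= cm_original

    def test_empty_feasible_set_raises(self, signal1):
        spec = IGSTSearchSpec(
            m_range=(3.0, 3.0), p_range=(3.0, 3.0), r_range=(1.0, 1.0), step=1.0
        )
        with pytest.raises(ValueError):
            wm.optimize_igst(signal1, spec)

    def test_constants_match_width_bounds(self):
        assert (ALPHA, BETA) == (10.0, 1000.0)
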