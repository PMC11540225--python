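import numpy as np
import pytest

import wvmask as wm


@pytest.fixture(scope="session")
def signal1():
    return wm.generate_signal1()


@pytest.fixture(scope="session")
def signal2():
    return wm.generate_signal2()


@pytest.fixture
def tone():
    """Factory for pure cosine test tones."""

    def make(freq_hz, fs=500.0, n=500, amp=1.0):
        t = np.arange(n) / fs
        return wm.SampledSignal(amp * np.cos(2 * np.pi * freq_hz * t), fs=fs)

    return make


@pytest.fixture(scope="session")
def igst_signal1():
    """Reference IGST window for clean signal 1 (concentration-search optimum)."""
    return wm.STWindowModel("igst", m=1.0452, p=0.9908, r=0.6956)


@pytest.fixture(scope="session")
def igst_signal2():
    return wm.STWindowModel("igst", m=1.0063, p=0.9914, r=0.6979)
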