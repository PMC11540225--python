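"""ECG pre-conditioning: notch cascade plus bandpass, on synthetic tones.

The chain removes mains hum (60/120/180 Hz notches), baseline drift
(below 0.25 Hz) and muscle noise (above 40 Hz) while passing the ECG
band unchanged, with zero phase so wave morphology is preserved.
"""

import numpy as np

from wvmask import SampledSignal, ecg_preprocess

fs = 600.0
t = np.arange(int(10 * fs)) / fs
rms = lambda x: float(np.sqrt(np.mean(np.asarray(x) ** 2)))

for label, x in [
    ("60 Hz mains hum", np.cos(2 * np.pi * 60 * t)),
    ("10 Hz in-band tone", np.cos(2 * np.pi * 10 * t)),
    ("DC offset", np.ones(t.size)),
]:
    out = ecg_preprocess(SampledSignal(x, fs=fs))
    gain_db = 20 * np.log10(max(rms(out.samples), 1e-300) / rms(x))
    print(f"{label:20s} -> gain {gain_db:8.2f} dB")
print()
print("hum and DC are strongly attenuated; the in-band tone passes at ~0 dB")
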