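"""Reproduce the clean signal-1 concentration comparison table.

For the clean benchmark signal 1: compute the WVD, the four masking TFRs
(STFT modulus and three S-transform variants), and the four masked WVDs,
then report the concentration measure (higher = more concentrated) and
order-3 Rényi entropy (lower = more concentrated) for each.
"""

from wvmask import STWindowModel, generate_signal1
from wvmask.masking import evaluate_pipeline

igst = STWindowModel("igst", m=1.0452, p=0.9908, r=0.6956)
table = evaluate_pipeline(generate_signal1(), igst_model=igst)

print(f"{'TFR':16s} {'CM x10^-3':>10s} {'RE (bits)':>10s}")
for _, row in table.iterrows():
    label = "WVD" if row.role == "wvd" else f"{row.role} ({row.method})"
    print(f"{label:16s} {row.cm * 1e3:10.4f} {row.re:10.4f}")
print()
print("every masked WVD is more concentrated than the raw WVD (higher CM,")
print("lower RE); the original-ST mask is the weakest of the four masks")
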