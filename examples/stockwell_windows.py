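"""Compare S-transform window laws and search for the best IGST window.

The S-transform variants differ only in how the Gaussian window width
sigma_f shrinks with frequency.  The IGST triple (m, p, r) must keep the
window between 10 and 1000 samples wide across the band; the best triple
maximizes the concentration measure of the resulting transform.
"""

from wvmask import (
    IGSTSearchSpec,
    STWindowModel,
    check_igst_constraints,
    generate_signal1,
    mst_model,
    optimize_igst,
    sigma_f,
)

sig = generate_signal1()
models = {
    "original ST": STWindowModel("original"),
    "IGST (reference)": STWindowModel("igst", m=1.0452, p=0.9908, r=0.6956),
    "MST (gamma=4)": mst_model(sig, gamma=4.0),
}
print("window standard deviation sigma_f in ms:")
print(f"{'variant':18s} {'f=10 Hz':>9s} {'f=150 Hz':>9s} {'f=250 Hz':>9s}")
for name, model in models.items():
    vals = [1e3 * float(sigma_f(model, f)) for f in (10.0, 150.0, 250.0)]
    print(f"{name:18s} {vals[0]:9.2f} {vals[1]:9.2f} {vals[2]:9.2f}")

ok, (hi, lo) = check_igst_constraints(1.0452, 0.9908, 0.6956, fs=500.0)
print(f"\nreference IGST triple feasible: {ok} (slacks {hi:.3f}, {lo:.3f} <= 0)")

model, cm = optimize_igst(sig, IGSTSearchSpec(step=0.25))
print(
    f"coarse concentration search picks m={model.m:g}, p={model.p:g}, "
    f"r={model.r:g} with CM = {cm * 1e3:.4f} x10^-3"
)
print("(the original ST window 1/f is itself outside the feasible region)")
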