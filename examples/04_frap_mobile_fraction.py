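"""FRAP: mobile/stable fraction and recovery-rate fitting.

Simulates two recovery curves — a control and a "treated" membrane with
a larger stable fraction — and fits the single-exponential model
I(t) = I0 + (Iinf − I0)(1 − e^(−k t)) to each.
"""

from memclust import fit_frap, normalize_frap
from memclust.synthetic import FRAPSpec, generate_frap_curve

for name, mobile in [("control", 0.75), ("treated", 0.55)]:
    spec = FRAPSpec(prebleach_level=1200.0, bleach_depth=0.8,
                    mobile_fraction=mobile, rate_k=0.2,
                    duration=60.0, sample_interval=0.5,
                    noise_sd=10.0, seed=5)
    fit = fit_frap(normalize_frap(generate_frap_curve(spec)))
    print(f"{name:8s}: mobile = {fit.mobile_fraction:.2f}, "
          f"stable = {fit.stable_fraction:.2f}, k = {fit.rate_k:.3f} /s")

print("-> the treated membrane recovers less fluorescence: a ~20-point")
print("   upregulation of the stable (immobile) fraction, the signature of")
print("   proteins trapped in condensed nanodomains.")
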