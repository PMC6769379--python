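"""Charge displacement between transporter states from capacitor fits.

Simulates membrane voltages as a linear function of the imposed ionic
charge imbalance for two protein states, fits V = (q_sol + q_p0)/C0 per
state by least squares, and reports the effective charge moved between
the states in units of e0 -- the quantity that determines the sign of the
capacitive current a binding or translocation step generates.
"""

import numpy as np

import kgate

fits = {}
for name, q_p0, seed in (("outward, ion bound", 1.0, 20),
                         ("inward, ion bound", 0.5, 21)):
    series = kgate.gen_capacitor_series(
        q_p0=q_p0, c0=0.05, q_sol_values=np.linspace(-12, -6, 7),
        noise_sd=3.0, n_replicates=6, seed=seed, state=name)
    fits[name] = kgate.fit_capacitor_response(series, n_boot=1000,
                                              seed=seed + 100)
    f = fits[name]
    print(f"{name}: q_p0 = {f.q_p0:.3f} +- {f.sd_q_p0:.3f} e0, "
          f"C0 = {f.c0:.4f} e0/mV")

dq, sd = kgate.charge_displacement(fits["outward, ion bound"],
                                   fits["inward, ion bound"])
print(f"translocation charge displacement: {dq:.3f} +- {sd:.3f} e0 "
      "(truth: -0.5)")
print("A negative displacement moves negative charge outward -- an")
print("outward capacitive current upon inward translocation.")
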