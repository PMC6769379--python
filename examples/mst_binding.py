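"""Non-parametric MST binding-curve comparison of wild type and mutant.

Generates replicate thermophoresis binding curves for a wild-type protein
(K_D = 5 mM) and a binding-impaired mutant (K_D = 50 mM), fits each set by
Nadaraya-Watson kernel regression on the log-concentration axis with 99%
bootstrap bands, and tests whether the curves differ significantly by
confidence-band separation.
"""

import numpy as np

import kgate

conc = 0.5 * 2.0 ** np.arange(12)  # serial 1:2 dilution, mM
fits = {}
for name, kd, seed in (("WT", 5.0, 30), ("mutant", 50.0, 31)):
    curves = kgate.gen_mst_curves(kd=kd, amplitude=-0.25, baseline=1.0,
                                  concentrations=conc, noise_sd=0.01,
                                  n_curves=4, seed=seed)
    fits[name] = kgate.nw_fit_with_ci(curves, n_boot=10_000, seed=seed + 100)
    mid = len(fits[name].grid) // 2
    print(f"{name}: bandwidth {fits[name].bandwidth:.3f} (log10 mM), "
          f"fit at {10 ** fits[name].grid[mid]:.1f} mM = "
          f"{fits[name].mean[mid]:.3f}")

flags, significant, grid = kgate.ci_overlap_test(fits["WT"], fits["mutant"])
frac = flags.mean()
print(f"non-overlapping 99% bands at {100 * frac:.0f}% of the grid "
      f"-> significant difference: {significant}")
print("A contiguous stretch of separated bands marks the K_D shift the")
print("mutation causes; isolated single-point separations are ignored.")
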