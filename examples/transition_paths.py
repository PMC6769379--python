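"""Reactive-flux pathways of ion binding through transient sites.

Builds a kinetic model in which the ion reaches the buried K1 site mostly
by first touching the superficial K2 (and sometimes K3) site, then runs
transition-path analysis: stationary occupancies, committors, and the
pathways ranked by reactive flux from the apo to the K1-bound state.
"""

import numpy as np

import kgate
from kgate.kinetics import KineticModel

# states: 0 apo, 1 K1-bound, 2 K2-bound, 3 K3-bound
rates = np.zeros((4, 4))
rates[0, 2], rates[2, 0] = 5.0, 2.0    # fast transient K2 association
rates[2, 1], rates[1, 2] = 4.0, 0.1    # K2 -> K1 relay
rates[0, 3], rates[3, 0] = 1.0, 1.5
rates[3, 1], rates[1, 3] = 0.8, 0.05   # secondary K3 -> K1 relay
rates[0, 1], rates[1, 0] = 0.02, 0.01  # direct binding is rare

model = KineticModel.from_rates(("K1", "K2", "K3"), rates)
dec = kgate.reactive_flux_paths(model, source_states=[0], sink_states=[1],
                                n_paths=3)
labels = ["apo", "K1", "K2", "K3"]
print("equilibrium occupancy:",
      {labels[i]: round(float(p), 3) for i, p in enumerate(dec.pi)})
print("forward committor:    ",
      {labels[i]: round(float(q), 3) for i, q in enumerate(dec.committor)})
print(f"total apo->K1 reactive flux: {dec.total_flux:.4f} /us")
for path, flux in dec.paths:
    names = "->".join(labels[s] for s in path)
    print(f"  path {names}: flux {flux:.4f} ({100 * flux / dec.total_flux:.0f}%)")
print("The two dominant pathways route through the transient K2 and K3")
print("sites; direct association carries almost no flux.")
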