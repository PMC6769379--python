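# End-to-end demo pipeline: binding kinetics -> transition paths,
# plus the free-energy, gating, charge and MST assays, all on synthetic
# data with known ground truth.  Every stochastic stage carries a seed.
stages:
  - stage: simulate_binding
    kd_mm: 30.0
    duration_us: 120.0
    dt_us: 0.002
    n_monomers: 6
    seed: 11
  - stage: kinetics
    site: K1
    n_boot: 1000
    seed: 12
  - stage: tpt
    sink: [K1]
  - stage: cgi
    dg: 19.7
    n: 250
    n_boot: 1000
    seed: 13
  - stage: gating
    closed_apo: 0.071
    closed_bound: 0.59
    n_windows: 44
    n_per_window: 2000
    n_boot: 30
    seed: 14
  - stage: charge
    states:
      - {name: ofc_bound, q_p0: 1.0}
      - {name: ifc_bound, q_p0: 0.5}
    n_boot: 1000
    seed: 15
  - stage: mst
    conditions:
      - {name: wt, kd_mm: 5.0}
      - {name: mutant, kd_mm: 50.0}
    n_boot: 2000
    seed: 16
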