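"""Reference parameter-recovery studies on synthetic ground truth.

Each function wires a generator to the matching estimator under the
package's reference study conditions (sample sizes and noise levels chosen
to emulate the source simulation campaigns at desk scale) and reports the
recovered quantity next to the generating truth.  They are used by the
validation suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import alchemy, kinetics, occupancy, pmfgate, synthgen


def kd_recovery(kd_mm: float, seed, n_monomers: int = 20,
                target_events: int = 500, concentration: float = 1.0,
                n_boot: int = 1000) -> dict:
    """Recover a dissociation constant from synthetic binding trajectories.

    A two-state binding scheme is Gillespie-simulated with the requested
    K_D at the given bulk concentration; the trace duration is set so the
    expected number of binding events is ``target_events``.  The off rate
    and frame spacing are regime-dependent so that both dwell times stay
    well resolved on the frame grid (fast unbound excursions in the
    high-affinity regime, short bound dwells in the low-affinity one).
    """
    if kd_mm <= 100.0:            # high affinity: unbound dwells are short
        k_off, dt = 0.1, 0.002
    else:                         # low affinity: dwells are comparable
        k_off, dt = 0.3, 0.01
    spec = synthgen.RateSpec.two_state(kd_mm=kd_mm, k_off=k_off,
                                       concentration=concentration)
    k_on = spec.rates[("apo", "K1")]
    cycle = 1.0 / k_on + 1.0 / k_off
    duration = target_events * cycle / n_monomers
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=2)
    traces = synthgen.gen_binding_traj(spec, duration=duration, dt=dt,
                                       n_monomers=n_monomers, seed=sub[0])
    occs = [occupancy.discretize_trajectory(t.trajectory) for t in traces]
    census = occupancy.transition_census(occs)
    model = kinetics.estimate_rate_matrix(census)
    est = kinetics.dissociation_constants(model, "K1", n_boot=n_boot,
                                          seed=sub[1])
    return {
        "true_kd_mm": kd_mm,
        "kd_mm": est.kd_mm,
        "sd_mm": est.sd_mm,
        "ci_mm": est.ci,
        "covered": est.ci[0] <= kd_mm <= est.ci[1],
        "n_events": est.n_on,
    }


def cgi_recovery(dg: float, seed, sigma: float = 4.0, n: int = 250,
                 temperature: float = 310.0, n_boot: int = 1000) -> dict:
    """Recover a free-energy difference by CGI from Crooks-consistent works."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=2)
    works = synthgen.gen_work_samples(dg, sigma, n, n, temperature, seed=sub[0])
    est = alchemy.cgi_estimate(works, n_boot=n_boot, seed=sub[1])
    return {"true_dg": dg, "dg": est.dg, "sd": est.sd,
            "method": est.method, "converged": est.converged, "n": 2 * n}


def ddg_recovery(dg_a: float, dg_b: float, seed, sigma: float = 4.0,
                 n: int = 250, temperature: float = 310.0,
                 n_boot: int = 1000) -> dict:
    """Recover a double free-energy difference from two synthetic CGI legs.

    Leg A plays the ligand-bound transformation, leg B the apo one; the
    reported quantity is the shift in binding free energy.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=4)
    wa = synthgen.gen_work_samples(dg_a, sigma, n, n, temperature, seed=sub[0])
    wb = synthgen.gen_work_samples(dg_b, sigma, n, n, temperature, seed=sub[1])
    ea = alchemy.cgi_estimate(wa, n_boot=n_boot, seed=sub[2])
    eb = alchemy.cgi_estimate(wb, n_boot=n_boot, seed=sub[3])
    ddg, sd = alchemy.double_difference(ea, eb)
    return {"true_ddg": dg_a - dg_b, "ddg": ddg, "sd": sd, "n": 4 * n}


def gating_recovery(closed_fraction: float, seed, n_windows: int = 44,
                    force_constant: float = 1000.0, n_per_window: int = 9000,
                    n_boot: int = 50) -> dict:
    """Recover a closed-gate probability via umbrella sampling + WHAM.

    An analytic double-well gate profile is calibrated so its Boltzmann
    closed-basin mass equals ``closed_fraction``; harmonically biased
    windows are sampled, the profile reconstructed by WHAM, the
    open/closed boundary located at the inter-basin density minimum, and
    the closed probability integrated with a bootstrap SE.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=2)
    pmf = synthgen.calibrate_double_well(closed_fraction)
    centers = np.linspace(pmf.domain[0], pmf.domain[1], n_windows)
    uset = synthgen.gen_umbrella_set(pmf, centers, force_constant,
                                     n_per_window, seed=sub[0])
    prof = pmfgate.wham_profile(uset, n_boot=n_boot, seed=sub[1])
    boundary = pmfgate.find_gate_boundary(prof.p, prof.x)
    stats = pmfgate.closed_probability(prof, boundary)
    return {
        "true_p_closed": closed_fraction,
        "p_closed": stats.p_closed,
        "sd": stats.sd,
        "boundary": boundary,
        "true_boundary": pmf.density_minimum(),
        "n": n_windows * n_per_window,
        "wham_converged": prof.converged,
    }
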