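"""Linear capacitor model of membrane voltage vs ionic charge imbalance.

In a double-bilayer computational electrophysiology setup the membrane
voltage responds linearly to the imposed ionic charge imbalance q_sol,

    V = (q_sol + q_p0) / C0,

where q_p0 is the protein's contribution to the capacitor charge in the
given conformational/occupancy state and C0 the total membrane/protein
capacitance.  q_p0 is obtained by ordinary least squares; differences of
q_p0 between states give the effective charge displaced by binding or
translocation, in units of e0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CapacitorSeries:
    """(charge imbalance, voltage) records with replicate identity."""

    q_sol: np.ndarray            # e0
    voltage: np.ndarray          # mV
    replicate: np.ndarray        # replicate (trajectory) id per record
    state: str = ""

    def __post_init__(self):
        self.q_sol = np.asarray(self.q_sol, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.q_sol) == len(self.voltage) == len(self.replicate)):
            raise ValueError("record arrays must have equal length")
        if len(np.unique(self.q_sol)) < 2:
            raise ValueError("need >= 2 distinct charge-imbalance values")


@dataclass
class ChargeFit:
    """Fitted capacitance and protein charge with bootstrap uncertainty."""

    c0: float                    # e0/mV
    q_p0: float                  # e0
    sd_q_p0: float
    residuals: np.ndarray
    state: str = ""
    bootstrap: np.ndarray | None = None


def _ols(q_sol, voltage):
    slope, intercept = np.polyfit(q_sol, voltage, 1)
    return slope, intercept


def fit_capacitor_response(series: CapacitorSeries, n_boot: int = 1000,
                           seed=None) -> ChargeFit:
    """Least-squares fit of V = a q_sol + b; C0 = 1/a, q_p0 = b/a.

    A non-positive slope is rejected as unphysical capacitance.  The
    bootstrap resamples complete replicate trajectories (never individual
    records), mirroring how independent samples arise in the simulations.
    """
    slope, intercept = _ols(series.q_sol, series.voltage)
    if slope <= 0:
        raise ValueError(f"non-physical capacitance: fitted slope {slope:.3g} "
                         "mV/e0 is not positive")
    c0 = 1.0 / slope
    q_p0 = intercept / slope
    residuals = series.voltage - (slope * series.q_sol + intercept)

    reps = np.unique(series.replicate)
    boots = None
    sd = 0.0
    if len(reps) > 1 and n_boot > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            pick = reps[rng.integers(0, len(reps), size=len(reps))]
            mask = np.concatenate([np.flatnonzero(series.replicate == r)
                                   for r in pick])
            s, b = _ols(series.q_sol[mask], series.voltage[mask])
            boots[k] = b / s
        sd = float(boots.std(ddof=1))
    return ChargeFit(c0, float(q_p0), sd, residuals, series.state, boots)


def charge_displacement(fit_state0: ChargeFit, fit_state1: ChargeFit):
    """Effective charge moved between two states: dq = q_p0(1) - q_p0(0).

    SD by quadrature of the two bootstrap SDs (the states come from
    independent simulations).  Returns (dq, sd) in e0.
    """
    dq = fit_state1.q_p0 - fit_state0.q_p0
    sd = float(np.hypot(fit_state0.sd_q_p0, fit_state1.sd_q_p0))
    return float(dq), sd


def displacement_matrix(fits: dict[str, ChargeFit]):
    """Pairwise q_p0 differences across labelled states.

    Returns ``{(state_a, state_b): (dq, sd)}`` for every ordered pair --
    the binding / translocation / dissociation legs of a transport cycle
    read directly off this table.
    """
    out = {}
    for a, fa in fits.items():
        for b, fb in fits.items():
            if a != b:
                out[(a, b)] = charge_displacement(fa, fb)
    return out
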