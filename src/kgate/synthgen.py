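"""Synthetic-data generators with known ground truth.

Every downstream stage of the package has a generator here that emulates
the statistical structure of the corresponding simulation or assay data:

- continuous-time Markov binding/unbinding with per-site distance emission
  (exact event-driven Gillespie sampling, hidden state path returned);
- overdamped Langevin dynamics on an analytic 1-D free-energy profile;
- Gaussian forward/reverse work distributions satisfying the Crooks
  fluctuation relation;
- Boltzmann-distributed umbrella-window samples on an analytic profile;
- linear capacitor voltage responses with replicate noise;
- Hill-shaped MST binding curves with replicate noise.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .alchemy import WorkSet
from .constants import DEFAULT_TEMPERATURE, kt
from .electromap import CapacitorSeries
from .mstfit import MSTCurveSet
from .occupancy import (DEFAULT_THRESHOLD, DistanceTrajectory,
                        canonical_site_order)
from .pmfgate import UmbrellaSet, UmbrellaWindow

# ---------------------------------------------------------------------------
# binding trajectories


@dataclass
class RateSpec:
    """Ground-truth kinetic scheme for binding-trajectory generation.

    States are labelled 'apo' or '+'-joined bound-site names ('K1',
    'K1+K2'); rates are first-order transition rates in 1/us at the stated
    bulk concentration.  Emission parameters: a bound site emits distances
    from a Normal(bound_mean, bound_sd) truncated below the discretization
    threshold; an unbound site follows an Ornstein-Uhlenbeck excursion
    process (mean/SD/correlation time below) reflected at threshold+0.5 A,
    so discretization recovers the hidden path exactly.
    """

    states: list[str]
    rates: dict = field(default_factory=dict)   # (state_i, state_j) -> 1/us
    concentration: float = 1.0                  # M
    threshold: float = DEFAULT_THRESHOLD        # A
    bound_mean: float = 3.0
    bound_sd: float = 0.15
    unbound_mean: float = 15.0
    unbound_sd: float = 5.0
    unbound_tau: float = 0.05                   # us, OU correlation time

    def __post_init__(self):
        if not self.states:
            raise ValueError("empty state set")
        for (a, b), r in self.rates.items():
            if a == b:
                raise ValueError(f"self-transition {a}->{b}")
            if r < 0:
                raise ValueError(f"negative rate {a}->{b}")
            for s in (a, b):
                if s not in self.states:
                    raise ValueError(f"rate references unknown state {s!r}")
        if self.bound_mean >= self.threshold:
            raise ValueError("bound emission mean must lie below threshold")
        if all(r == 0 for r in self.rates.values()) and len(self.states) > 1:
            warnings.warn("all rates are zero: degenerate spec, the initial "
                          "state is absorbing")

    @property
    def sites(self) -> tuple[str, ...]:
        names = set()
        for s in self.states:
            if s != "apo":
                names.update(s.split("+"))
        return canonical_site_order(names)

    def max_rate(self) -> float:
        out = {}
        for (a, _), r in self.rates.items():
            out[a] = out.get(a, 0.0) + r
        return max(out.values(), default=0.0)

    @classmethod
    def two_state(cls, site: str = "K1", kd_mm: float = 8.0,
                  k_off: float = 0.1, concentration: float = 1.0, **kw):
        """Apo <-> bound scheme with K_D fixed by the on/off rate ratio.

        The pseudo-first-order on rate is k_on = k_off * C / K_D, so the
        second-order on rate k_on / C and the off rate reproduce the
        requested dissociation constant exactly.
        """
        k_on = k_off * concentration / (kd_mm * 1e-3)
        return cls(states=["apo", site],
                   rates={("apo", site): k_on, (site, "apo"): k_off},
                   concentration=concentration, **kw)


@dataclass
class BindingTrace:
    """A synthetic distance trajectory plus its hidden ground truth."""

    trajectory: DistanceTrajectory
    hidden_states: np.ndarray        # encoded occupancy per frame
    jump_times: np.ndarray           # us, event-driven jump chain
    jump_states: np.ndarray          # state-label indices of the jump chain


def simulate_ctmc(spec: RateSpec, duration: float, rng,
                  initial: str = "apo"):
    """Exact event-driven (Gillespie) jump chain over [0, duration].

    Returns (jump_times, jump_state_indices); the state at time t is the
    one entered at the latest jump time <= t.
    """
    states = spec.states
    idx = {s: i for i, s in enumerate(states)}
    out = {s: [] for s in states}
    for (a, b), r in spec.rates.items():
        if r > 0:
            out[a].append((r, b))
    t = 0.0
    cur = initial
    times = [0.0]
    seq = [idx[cur]]
    while True:
        total = sum(r for r, _ in out[cur])
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        u = rng.uniform(0, total)
        acc = 0.0
        for r, b in out[cur]:
            acc += r
            if u < acc:
                cur = b
                break
        times.append(t)
        seq.append(idx[cur])
    return np.asarray(times), np.asarray(seq, dtype=int)


def _emit_distances(spec: RateSpec, bound_mask: np.ndarray, dt: float, rng):
    """Per-site distance emission for one monomer.

    Bound frames: iid truncated normal below the threshold.  Unbound
    frames: a stationary AR(1) discretization of the Ornstein-Uhlenbeck
    excursion process, reflected at the threshold + 0.5 A floor.
    """
    n = len(bound_mask)
    phi = np.exp(-dt / spec.unbound_tau)
    eps = rng.standard_normal(n) * spec.unbound_sd * np.sqrt(1 - phi ** 2)
    eps[0] = rng.standard_normal() * spec.unbound_sd
    ou = spec.unbound_mean + lfilter([1.0], [1.0, -phi], eps)
    floor = spec.threshold + 0.5
    dist = floor + np.abs(ou - floor)
    nb = int(bound_mask.sum())
    if nb:
        b = (spec.threshold - spec.bound_mean) / spec.bound_sd
        dist[bound_mask] = truncnorm.rvs(-np.inf, b, loc=spec.bound_mean,
                                         scale=spec.bound_sd, size=nb,
                                         random_state=rng)
    return dist


def gen_binding_traj(spec: RateSpec, duration: float, dt: float,
                     n_monomers: int = 1, seed=None,
                     initial: str = "apo") -> list[BindingTrace]:
    """Synthetic per-monomer distance trajectories from a CTMC ground truth.

    The jump chain is sampled exactly (event-driven) and read out on the
    frame grid; per-site distances are then emitted around the hidden
    occupancy.  Requires dt well below the fastest mean dwell (a warning is
    raised above 1/10 of it, since grid read-out starts to miss short
    excursions).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    mr = spec.max_rate()
    if mr > 0 and dt > 0.1 / mr:
        warnings.warn(f"dt={dt} is coarse relative to the fastest state "
                      f"(mean dwell {1 / mr:.3g} us); short events will be "
                      "missed")
    rng = np.random.default_rng(seed)
    sites = spec.sites
    site_bits = {s: b for b, s in enumerate(sites)}
    state_code = np.array([0 if s == "apo" else
                           sum(1 << site_bits[p] for p in s.split("+"))
                           for s in spec.states], dtype=np.int64)
    grid = np.arange(int(round(duration / dt))) * dt
    traces = []
    for m in range(n_monomers):
        jt, js = simulate_ctmc(spec, duration, rng, initial=initial)
        at = np.searchsorted(jt, grid, side="right") - 1
        hidden = state_code[js[at]]
        distances = {}
        for s in sites:
            bound = (hidden >> site_bits[s] & 1).astype(bool)
            distances[s] = _emit_distances(spec, bound, dt, rng)
        traj = DistanceTrajectory(f"monomer-{m}", dt, distances,
                                  concentration=spec.concentration)
        traces.append(BindingTrace(traj, hidden, jt, js))
    return traces


# ---------------------------------------------------------------------------
# analytic free-energy profiles and Langevin traces


@dataclass
class AnalyticPMF:
    """Polynomial 1-D free-energy profile G(x) over a bounded domain.

    ``coeffs`` are ascending polynomial coefficients of G in kJ/mol with x
    in nm; the Boltzmann density is normalized over ``domain``.
    """

    coeffs: np.ndarray
    domain: tuple[float, float]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("empty domain")
        g = self.g(np.linspace(lo, hi, 1001))
        if not np.isfinite(g).all():
            raise ValueError("G must be finite on the domain")

    def g(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coeffs)

    def dg(self, x):
        der = np.polynomial.polynomial.polyder(self.coeffs)
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), der)

    def boltzmann_density(self, grid):
        """Normalized Boltzmann density on the given grid."""
        g = self.g(grid)
        w = np.exp(-(g - g.min()) / kt(self.temperature))
        return w / np.trapezoid(w, grid)

    def basin_fraction(self, boundary: float, n: int = 20001) -> float:
        """Boltzmann mass of the region x < boundary (quadrature)."""
        lo, hi = self.domain
        grid = np.linspace(lo, hi, n)
        p = self.boltzmann_density(grid)
        mask = grid < boundary
        return float(np.trapezoid(p[mask], grid[mask]))

    def density_minimum(self) -> float:
        """Interior minimum of the Boltzmann density (= maximum of G)."""
        lo, hi = self.domain
        grid = np.linspace(lo, hi, 20001)
        g = self.g(grid)
        interior = (g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])
        idx = np.flatnonzero(interior)
        if len(idx) == 0:
            raise ValueError("profile has no interior barrier")
        return float(grid[idx[0] + 1])


def double_well(barrier: float = 15.0, well: float = 0.6, tilt: float = 0.0,
                domain=(-1.1, 1.1),
                temperature: float = DEFAULT_TEMPERATURE) -> AnalyticPMF:
    """Quartic double well G(x) = barrier ((x/well)^2 - 1)^2 + tilt x."""
    a = barrier / well ** 4
    coeffs = np.array([barrier, tilt, -2 * barrier / well ** 2, 0.0, a])
    return AnalyticPMF(coeffs, domain, temperature)


def calibrate_double_well(closed_fraction: float, barrier: float = 15.0,
                          well: float = 0.6, domain=(-1.1, 1.1),
                          temperature: float = DEFAULT_TEMPERATURE,
                          ) -> AnalyticPMF:
    """Double well whose closed-basin Boltzmann mass equals a target.

    'Closed' is the basin at small coordinate values, delimited by the
    interior barrier top.  The linear tilt is found by root bracketing so
    that the quadrature basin fraction matches ``closed_fraction``.
    """
    if not 0 < closed_fraction < 1:
        raise ValueError("closed fraction must be in (0, 1)")

    def frac(tilt):
        pmf = double_well(barrier, well, tilt, domain, temperature)
        return pmf.basin_fraction(pmf.density_minimum()) - closed_fraction

    span = 4.0 * kt(temperature) / well
    lo, hi = -span, span
    for _ in range(30):
        if frac(lo) * frac(hi) < 0:
            break
        lo *= 2
        hi *= 2
    tilt = brentq(frac, lo, hi, xtol=1e-10)
    return double_well(barrier, well, tilt, domain, temperature)


def gen_langevin_trace(pmf: AnalyticPMF, diffusion: float, dt: float,
                       n_steps: int, seed=None, x0=None) -> np.ndarray:
    """Overdamped Langevin trajectory on the analytic profile.

    Euler-Maruyama integration of dx = -beta D G'(x) dt + sqrt(2 D dt) xi
    with reflecting domain walls; the stationary histogram converges to the
    Boltzmann density of the profile.  Stability requires the deterministic
    step beta D |G'| dt to stay well below the domain size; dt should be
    below ~0.1 kT / (D max|G''|).  Units: x nm, D nm^2/ns, dt ns.
    """
    if dt <= 0 or n_steps <= 0:
        raise ValueError("dt and n_steps must be positive")
    beta = 1.0 / kt(pmf.temperature)
    lo, hi = pmf.domain
    rng = np.random.default_rng(seed)
    x = np.empty(n_steps)
    cur = 0.5 * (lo + hi) if x0 is None else float(x0)
    noise = rng.standard_normal(n_steps) * np.sqrt(2 * diffusion * dt)
    # Horner evaluation on plain floats: the per-step cost dominates
    der = tuple(float(c) for c in
                np.polynomial.polynomial.polyder(pmf.coeffs))[::-1]
    mob = beta * diffusion * dt
    for i in range(n_steps):
        grad = 0.0
        for c in der:
            grad = grad * cur + c
        if not math.isfinite(grad):
            raise FloatingPointError(f"non-finite force at x={cur:.4g}")
        cur = cur - mob * grad + noise[i]
        # reflecting walls
        if cur < lo:
            cur = 2 * lo - cur
        if cur > hi:
            cur = 2 * hi - cur
        x[i] = cur
    return x


# ---------------------------------------------------------------------------
# Crooks-consistent work samples


def gen_work_samples(dg: float, sigma: float, n_forward: int, n_reverse: int,
                     temperature: float = DEFAULT_TEMPERATURE,
                     seed=None) -> WorkSet:
    """Gaussian work distributions satisfying the Crooks relation.

    Forward works ~ Normal(dg + sigma^2/(2 kT), sigma^2); negated reverse
    works ~ Normal(dg - sigma^2/(2 kT), sigma^2).  With a common variance
    the log density ratio ln[P_f(W)/P_r(-W)] is exactly beta (W - dg), the
    fluctuation relation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_forward < 2 or n_reverse < 2:
        raise ValueError("need >= 2 samples per direction")
    kt_ = kt(temperature)
    rng = np.random.default_rng(seed)
    shift = sigma ** 2 / (2 * kt_)
    forward = rng.normal(dg + shift, sigma, size=n_forward)
    reverse = rng.normal(dg - shift, sigma, size=n_reverse)
    return WorkSet(forward, reverse, temperature)


# ---------------------------------------------------------------------------
# umbrella windows


def gen_umbrella_set(pmf: AnalyticPMF, centers, force_constant: float,
                     n_per_window: int, seed=None,
                     min_overlap: float = 1e-3, n_grid: int = 4001,
                     ) -> UmbrellaSet:
    """Boltzmann samples from harmonically biased windows on the profile.

    Each window's samples are drawn exactly from the normalized density
    exp(-beta [G(x) + k/2 (x - c)^2]) by inverse-CDF interpolation on a
    dense grid.  Warns when adjacent biased densities overlap less than
    ``min_overlap`` (WHAM will be ill-conditioned) and when windows hold a
    single sample.
    """
    if force_constant <= 0:
        raise ValueError("force constant must be positive")
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    if n_per_window == 1:
        warnings.warn("1 sample per window: valid but severely low-sample")
    centers = np.asarray(centers, dtype=float)
    beta = 1.0 / kt(pmf.temperature)
    lo, hi = pmf.domain
    grid = np.linspace(lo, hi, n_grid)
    g = pmf.g(grid)
    rng = np.random.default_rng(seed)

    densities = []
    windows = []
    for c in np.sort(centers):
        u = g + 0.5 * force_constant * (grid - c) ** 2
        w = np.exp(-beta * (u - u.min()))
        dens = w / np.trapezoid(w, grid)
        densities.append(dens)
        cdf = np.concatenate(([0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))))
        cdf /= cdf[-1]
        samples = np.interp(rng.uniform(size=n_per_window), cdf, grid)
        windows.append(UmbrellaWindow(float(c), force_constant, samples))

    for d1, d2, w1, w2 in zip(densities[:-1], densities[1:],
                              windows[:-1], windows[1:]):
        ov = np.trapezoid(np.minimum(d1, d2), grid)
        if ov < min_overlap:
            warnings.warn(f"windows at {w1.center:.4g} and {w2.center:.4g} "
                          f"overlap only {ov:.2g}; WHAM may be "
                          "ill-conditioned")
    return UmbrellaSet(windows, temperature=pmf.temperature)


# ---------------------------------------------------------------------------
# capacitor series and MST curves


def gen_capacitor_series(q_p0: float, c0: float, q_sol_values,
                         noise_sd: float = 5.0, n_replicates: int = 5,
                         seed=None, state: str = "") -> CapacitorSeries:
    """Linear capacitor voltages V = (q_sol + q_p0)/C0 with replicate noise.

    Units: charges in e0, C0 in e0/mV, noise in mV.
    """
    if c0 <= 0:
        raise ValueError("capacitance must be positive")
    q_sol_values = np.asarray(q_sol_values, dtype=float)
    if len(np.unique(q_sol_values)) < 2:
        raise ValueError("need >= 2 distinct charge imbalances")
    rng = np.random.default_rng(seed)
    q = np.repeat(q_sol_values, n_replicates)
    rep = np.tile(np.arange(n_replicates), len(q_sol_values))
    v = (q + q_p0) / c0 + rng.normal(0.0, noise_sd, size=len(q))
    return CapacitorSeries(q, v, rep, state=state)


def gen_mst_curves(kd: float, amplitude: float, baseline: float,
                   concentrations, noise_sd: float = 0.005,
                   n_curves: int = 3, seed=None) -> MSTCurveSet:
    """Replicate MST binding curves with a hyperbolic (Hill n=1) shape.

    signal(c) = baseline + amplitude c/(c + kd) + noise, each replicate
    normalized to 1 at the lowest concentration (as the fitting stage
    expects).  kd and concentrations in mM.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0) or np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must be positive and increasing")
    rng = np.random.default_rng(seed)
    shape = baseline + amplitude * concentrations / (concentrations + kd)
    curves = shape[None, :] + rng.normal(
        0.0, noise_sd, size=(n_curves, len(concentrations)))
    curves = curves / curves[:, [0]]
    return MSTCurveSet(concentrations, curves)
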