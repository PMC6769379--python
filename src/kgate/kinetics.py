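"""Dwell-time maximum-likelihood kinetics and dissociation constants.

The rate from occupancy state *i* to *j* is estimated as k_ij = N_ij / t_i
(accumulated transition count over accumulated dwell time), the
maximum-likelihood estimator for first-order chemical reaction rates.
Site-level on/off rates pool all compound states that share the site's
occupancy bit; the dissociation constant is K_D = k_off / k_on(2nd order),
with the second-order on rate obtained by dividing the pseudo-first-order on
rate by the bulk concentration.  Errors come from bootstrap resampling of
complete monomer trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .occupancy import TransitionCensus, state_label


@dataclass
class KineticModel:
    """Maximum-likelihood rate matrix with per-site derived quantities.

    ``rates[i, j]`` is in 1/us; rows of states never visited are NaN and
    flagged in ``unvisited`` rather than silently zero.
    """

    site_order: tuple[str, ...]
    rates: np.ndarray
    concentration: float
    visited: np.ndarray
    census: TransitionCensus | None = None
    no_event_pairs: list = field(default_factory=list)

    @classmethod
    def from_rates(cls, site_order, rates, concentration=1.0):
        """Build a model directly from a known rate matrix (for analysis of
        hypothetical or ground-truth kinetic schemes)."""
        rates = np.asarray(rates, dtype=float)
        visited = np.ones(len(rates), dtype=bool)
        return cls(tuple(site_order), rates, concentration, visited)

    @property
    def n_states(self) -> int:
        return len(self.rates)

    def labels(self) -> list[str]:
        return [state_label(i, self.site_order) for i in range(self.n_states)]

    def generator(self) -> np.ndarray:
        """CTMC generator Q: off-diagonals k_ij, rows summing to zero.

        Unvisited states get zero rows (absorbing placeholders)."""
        q = np.where(np.isnan(self.rates), 0.0, self.rates).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def to_dict(self) -> dict:
        return {
            "sites": list(self.site_order),
            "states": self.labels(),
            "concentration_M": self.concentration,
            "rates_per_us": [[None if not np.isfinite(v) else v for v in row]
                             for row in self.rates],
        }


@dataclass
class KDEstimate:
    """Dissociation constant of one site with bootstrap uncertainty."""

    site: str
    kd_mm: float
    sd_mm: float
    ci: tuple[float, float]
    on_rate_2nd: float      # 1/us/M
    off_rate: float         # 1/us
    n_on: int
    n_off: int
    failed_fraction: float = 0.0
    bootstrap: np.ndarray | None = None


def estimate_rate_matrix(census: TransitionCensus) -> KineticModel:
    """ML rate matrix k_ij = N_ij / t_i from a transition census.

    States with zero dwell but outgoing counts are inconsistent input;
    states with zero dwell and zero counts are flagged unvisited (NaN row).
    """
    counts = census.counts
    dwell = census.dwell
    bad = (dwell == 0) & (counts.sum(axis=1) > 0)
    if bad.any():
        raise ValueError(f"states {np.flatnonzero(bad).tolist()} have transitions "
                         "but zero dwell time")
    visited = dwell > 0
    rates = np.full_like(counts, np.nan, dtype=float)
    rates[visited] = counts[visited] / dwell[visited, None]
    np.fill_diagonal(rates, 0.0)
    no_events = [(int(i), int(j)) for i, j in zip(*np.nonzero(
        visited[:, None] & visited[None, :] & (counts == 0)))
        if i != j]
    return KineticModel(census.site_order, rates, census.concentration,
                        visited, census, no_event_pairs=no_events)


def _site_rates(census: TransitionCensus, bit: int):
    """Aggregate pseudo-first-order on and off rates for one site bit.

    Binding = any transition that sets the bit, over time spent with the bit
    clear; unbinding = any transition that clears it, over time with it set.
    Returns (k_on_pseudo, k_off, n_on, n_off); rates are NaN when the
    corresponding dwell is zero.
    """
    idx = np.arange(census.n_states)
    has = (idx >> bit & 1).astype(bool)
    n_on = int(census.counts[np.ix_(~has, has)].sum())
    n_off = int(census.counts[np.ix_(has, ~has)].sum())
    t_off = census.dwell[~has].sum()
    t_on = census.dwell[has].sum()
    k_on = n_on / t_off if t_off > 0 else np.nan
    k_off = n_off / t_on if t_on > 0 else np.nan
    return k_on, k_off, n_on, n_off


def _kd_mm(census: TransitionCensus, bit: int) -> float:
    """Point K_D (mM) for a site: off rate over second-order on rate."""
    k_on, k_off, n_on, n_off = _site_rates(census, bit)
    if not np.isfinite(k_on) or n_on == 0:
        raise ZeroDivisionError("no binding events observed")
    k_on_2nd = k_on / census.concentration          # 1/us/M
    return k_off / k_on_2nd * 1e3                   # M -> mM


def dissociation_constants(model: KineticModel, site: str,
                           n_boot: int = 1000, seed=None) -> KDEstimate:
    """K_D of one site (mM) with SD from monomer-level bootstrap.

    Requires the model to carry its census (per-monomer statistics); raises
    when no binding events were observed -- use :func:`kd_upper_bound` then.
    """
    census = model.census
    if census is None:
        raise ValueError("model carries no census; K_D needs observed events")
    if site not in model.site_order:
        raise ValueError(f"unknown site {site!r}")
    bit = model.site_order.index(site)
    k_on, k_off, n_on, n_off = _site_rates(census, bit)
    if n_on == 0 or not np.isfinite(k_on):
        raise ValueError(f"no binding events for {site}; K_D undefined "
                         "(consider kd_upper_bound)")
    kd = _kd_mm(census, bit)

    rng = np.random.default_rng(seed)
    n_mon = census.n_monomers
    boots, failed = [], 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_mon, size=n_mon)
        try:
            boots.append(_kd_mm(census.resampled(pick), bit))
        except ZeroDivisionError:
            failed += 1
    boots = np.asarray(boots)
    if len(boots) < 2:
        raise ValueError("bootstrap failed on nearly all resamples")
    sd = float(boots.std(ddof=1))
    ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return KDEstimate(site, kd, sd, ci, k_on / census.concentration, k_off,
                      n_on, n_off, failed / n_boot, bootstrap=boots)


def kd_upper_bound(census: TransitionCensus, site: str, reference_site: str,
                   reference_kd_mm: float) -> dict:
    """Upper bound on a site's K_D when unbinding was never observed.

    Posits a single target->reference relocation event in the accumulated
    target-bound dwell time (k_out_max = 1 / t_bound), combines it with the
    observed reference->target relocation rate k_in, and scales the
    reference site's K_D by the implied equilibrium constant:

        K_D(target) <= K_D(reference) * k_out_max / k_in

    Returns the bound together with an explicit assumption log; the bound is
    a construction from stated inputs, not a measured quantity.
    """
    so = census.site_order
    if site not in so or reference_site not in so:
        raise ValueError("site names not present in census")
    bit = so.index(site)
    rbit = so.index(reference_site)
    idx = np.arange(census.n_states)
    has_t = (idx >> bit & 1).astype(bool)
    has_r = (idx >> rbit & 1).astype(bool)
    t_bound = census.dwell[has_t].sum()
    if t_bound <= 0:
        raise ValueError(f"no dwell time in {site}-bound states")
    # relocation = reference occupied & target empty -> target occupied & reference empty
    src = ~has_t & has_r
    dst = has_t & ~has_r
    n_in = int(census.counts[np.ix_(src, dst)].sum())
    t_src = census.dwell[src].sum()
    if n_in == 0 or t_src <= 0:
        raise ValueError(f"no {reference_site}->{site} relocations observed; "
                         "bound undefined")
    k_in = n_in / t_src
    k_out_max = 1.0 / t_bound
    bound = reference_kd_mm * k_out_max / k_in
    return {
        "site": site,
        "upper_bound_mm": bound,
        "assumptions": [
            f"posited exactly one {site}->{reference_site} relocation in the "
            f"{t_bound:.3g} us of {site}-bound dwell time (k_out_max = "
            f"{k_out_max:.3g} /us)",
            f"observed {reference_site}->{site} relocation rate "
            f"{k_in:.3g} /us over {n_in} events",
            f"reference K_D({reference_site}) = {reference_kd_mm} mM",
        ],
    }


def bootstrap_kinetics(traces, statistic, n_boot: int = 1000, seed=None):
    """Bootstrap an arbitrary statistic over monomer trajectories.

    ``statistic`` maps a list of occupancy traces to a scalar; monomers are
    resampled with replacement (complete trajectories are the independent
    unit).  Returns (sd, (lo, hi), failed_fraction, samples).
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("need >= 2 monomer trajectories")
    rng = np.random.default_rng(seed)
    vals, failed = [], 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(traces), size=len(traces))
        try:
            vals.append(statistic([traces[i] for i in pick]))
        except Exception:
            failed += 1
    vals = np.asarray(vals, dtype=float)
    if n_boot < 2 or len(vals) < 2:
        warnings.warn("degenerate bootstrap (n_boot < 2); CI is meaningless")
        sd = 0.0
        ci = (float(vals[0]), float(vals[0])) if len(vals) else (np.nan, np.nan)
    else:
        sd = float(vals.std(ddof=1))
        ci = tuple(np.percentile(vals, [2.5, 97.5]))
    return sd, ci, failed / n_boot, vals
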