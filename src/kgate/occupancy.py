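"""Occupancy-state analysis of ion-site distance trajectories.

A transporter monomer is watched through the distance of the closest cation
to each interaction site (K1..K4).  Frames are discretized into bound /
unbound per site with a distance threshold, encoded into a compound
occupancy state (one bit per site), and reduced to dwell times and
transition counts -- the sufficient statistics for maximum-likelihood rate
estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Midpoint of the 3.3-3.65 A discretization range used for bound/unbound calls.
DEFAULT_THRESHOLD: float = 3.5


def canonical_site_order(sites) -> tuple[str, ...]:
    """Deterministic site ordering; bit *s* of the encoded state is site s.

    Lexicographic sorting puts K1 on bit 0, K2 on bit 1, ... which yields the
    conventional 8-state (three sites) or 16-state (four sites) tables.
    """
    return tuple(sorted(sites))


def state_label(code: int, site_order: tuple[str, ...]) -> str:
    """Human-readable label for an encoded occupancy state ('apo', 'K1+K2')."""
    on = [s for b, s in enumerate(site_order) if code >> b & 1]
    return "+".join(on) if on else "apo"


def label_to_state(label: str, site_order: tuple[str, ...]) -> int:
    """Inverse of :func:`state_label`."""
    if label == "apo":
        return 0
    code = 0
    for part in label.split("+"):
        if part not in site_order:
            raise ValueError(f"unknown site {part!r} (sites: {site_order})")
        code |= 1 << site_order.index(part)
    return code


@dataclass
class DistanceTrajectory:
    """Per-monomer time series of per-site ion distances.

    Parameters
    ----------
    monomer_id : identifier of the monomer the series was recorded from.
    dt : frame spacing in microseconds.
    distances : mapping site name -> distance series in Angstrom; the
        distance of the closest cation to the site's coordinating atoms.
    gate : optional HP1-HP2 gate distance series (Angstrom).
    concentration : bulk cation concentration in M.
    """

    monomer_id: str
    dt: float
    distances: dict[str, np.ndarray]
    gate: np.ndarray | None = None
    concentration: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.distances:
            raise ValueError("at least one site series required")
        self.distances = {k: np.asarray(v, dtype=float) for k, v in self.distances.items()}
        lengths = {len(v) for v in self.distances.values()}
        if len(lengths) != 1:
            raise ValueError("all site series must have equal length")
        if self.gate is not None:
            self.gate = np.asarray(self.gate, dtype=float)
            if len(self.gate) != self.n_frames:
                raise ValueError("gate series length mismatch")

    @property
    def sites(self) -> tuple[str, ...]:
        return canonical_site_order(self.distances)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.distances.values())))

    @property
    def duration(self) -> float:
        """Trace duration in microseconds (frames x dt)."""
        return self.n_frames * self.dt


@dataclass
class OccupancyTrace:
    """Discretized occupancy of a single monomer.

    ``states[t]`` has bit *s* set iff site ``site_order[s]`` is bound at
    frame *t* (distance <= threshold; ties count as bound).
    """

    monomer_id: str
    dt: float
    site_order: tuple[str, ...]
    bound: dict[str, np.ndarray]
    states: np.ndarray
    thresholds: dict[str, float]
    concentration: float = 1.0
    n_rejected: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt


@dataclass
class TransitionCensus:
    """Pooled dwell times and transition counts over a set of monomers.

    ``counts[i, j]`` is the number of observed i->j state changes and
    ``dwell[i]`` the accumulated residence time (us) in state *i*; these are
    the N_ij and t_i of the dwell-time maximum-likelihood rate estimator.
    Per-monomer statistics are retained so bootstrap resampling can treat
    complete monomeric trajectories as the independent sampling unit.
    """

    site_order: tuple[str, ...]
    counts: np.ndarray
    dwell: np.ndarray
    concentration: float
    per_monomer: list = field(default_factory=list)  # (counts, dwell) pairs

    @property
    def n_states(self) -> int:
        return len(self.dwell)

    @property
    def n_monomers(self) -> int:
        return len(self.per_monomer)

    @property
    def total_duration(self) -> float:
        return float(self.dwell.sum())

    def labels(self) -> list[str]:
        return [state_label(i, self.site_order) for i in range(self.n_states)]

    def resampled(self, indices) -> "TransitionCensus":
        """Census pooled over the given monomer indices (with repetition)."""
        counts = sum(self.per_monomer[i][0] for i in indices)
        dwell = sum(self.per_monomer[i][1] for i in indices)
        return TransitionCensus(self.site_order, counts, dwell, self.concentration,
                                per_monomer=[self.per_monomer[i] for i in indices])


def discretize_trajectory(traj: DistanceTrajectory,
                          thresholds: float | dict[str, float] | None = None,
                          ) -> OccupancyTrace:
    """Discretize per-site distances into a compound occupancy-state series.

    A frame is bound at a site when the distance is <= the site's threshold
    (the tie counts as bound, a deterministic rule).  Frames with non-finite
    distances at any site are rejected (dropped) and reported via
    ``n_rejected`` and a warning.
    """
    sites = traj.sites
    if thresholds is None:
        thr = {s: DEFAULT_THRESHOLD for s in sites}
    elif np.isscalar(thresholds):
        thr = {s: float(thresholds) for s in sites}
    else:
        missing = set(sites) - set(thresholds)
        if missing:
            raise ValueError(f"missing thresholds for sites {sorted(missing)}")
        thr = {s: float(thresholds[s]) for s in sites}
    for s, t in thr.items():
        if t <= 0:
            raise ValueError(f"threshold for {s} must be positive")

    stacked = np.vstack([traj.distances[s] for s in sites])
    finite = np.isfinite(stacked).all(axis=0)
    n_rejected = int((~finite).sum())
    if n_rejected:
        warnings.warn(f"{traj.monomer_id}: rejected {n_rejected} non-finite frames")
    stacked = stacked[:, finite]

    bound = {}
    states = np.zeros(stacked.shape[1], dtype=np.int64)
    for b, s in enumerate(sites):
        flags = stacked[b] <= thr[s]
        bound[s] = flags
        states |= flags.astype(np.int64) << b
    return OccupancyTrace(traj.monomer_id, traj.dt, sites, bound, states, thr,
                          concentration=traj.concentration, n_rejected=n_rejected)


def _runs(states: np.ndarray):
    """Run-length encode a state series -> (start, length, state) arrays."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(states)])))
    return starts, lengths, states[starts]


def _merge_short_runs(states: np.ndarray, min_dwell: int) -> np.ndarray:
    """Merge runs shorter than ``min_dwell`` frames into the flanking state.

    The longer flanking run wins; the earlier one on a tie.  Iterates until
    no short run remains (merging can create new short runs only by fusing,
    which grows runs, so this terminates).
    """
    states = states.copy()
    while True:
        starts, lengths, vals = _runs(states)
        short = np.flatnonzero(lengths < min_dwell)
        if len(short) == 0 or len(vals) == 1:
            return states
        i = short[0]
        if i == 0:
            j = 1
        elif i == len(vals) - 1:
            j = i - 1
        else:
            j = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
        states[starts[i]:starts[i] + lengths[i]] = vals[j]


def transition_census(traces, min_dwell: int = 0) -> TransitionCensus:
    """Pool dwell times and transition counts over monomer traces.

    ``min_dwell`` (frames) is an optional flicker filter: runs shorter than
    it are merged into the flanking state before counting (default 0, no
    filtering).  Dwell time is frame-based (each frame contributes dt to its
    state), so the dwell total equals the input duration exactly.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty trace set")
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    site_order = traces[0].site_order
    conc = traces[0].concentration
    n_states = 2 ** len(site_order)
    per_monomer = []
    for tr in traces:
        if tr.site_order != site_order:
            raise ValueError("traces have inconsistent site sets")
        states = tr.states
        if min_dwell > 0:
            states = _merge_short_runs(states, min_dwell)
        counts = np.zeros((n_states, n_states), dtype=np.int64)
        idx = np.flatnonzero(np.diff(states))
        np.add.at(counts, (states[idx], states[idx + 1]), 1)
        dwell = np.bincount(states, minlength=n_states).astype(float) * tr.dt
        per_monomer.append((counts, dwell))
    total_counts = sum(c for c, _ in per_monomer)
    total_dwell = sum(d for _, d in per_monomer)
    return TransitionCensus(site_order, total_counts, total_dwell, conc, per_monomer)


def binding_route_census(traces, target_site: str) -> dict[str, int]:
    """Classify how the target site becomes occupied.

    For each unbound->bound flip of the target site's flag the route is read
    off the occupancy state of the flanking frames:

    - ``second-ion``: another site is still occupied in the new frame (the
      target fills while an ion is parked elsewhere);
    - ``direct``: the preceding frame was apo;
    - ``via-<site>``: exactly one other site was occupied in the preceding
      frame and released (a relay, e.g. the K2 -> K1 hand-off);
    - ``via-multi``: several sites were occupied and all released at the flip.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty trace set")
    site_order = traces[0].site_order
    if target_site not in site_order:
        raise ValueError(f"target site {target_site!r} not present")
    bit = site_order.index(target_site)
    routes: dict[str, int] = {}
    for tr in traces:
        on = (tr.states >> bit) & 1
        flips = np.flatnonzero((on[1:] == 1) & (on[:-1] == 0)) + 1
        for f in flips:
            prev, new = int(tr.states[f - 1]), int(tr.states[f])
            others_new = new & ~(1 << bit)
            others_prev = prev & ~(1 << bit)
            if others_new:
                route = "second-ion"
            elif others_prev == 0:
                route = "direct"
            else:
                occupied = [s for b, s in enumerate(site_order)
                            if others_prev >> b & 1]
                route = f"via-{occupied[0]}" if len(occupied) == 1 else "via-multi"
            routes[route] = routes.get(route, 0) + 1
    return routes
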