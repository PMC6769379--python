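"""Transition-path theory on the estimated kinetic model.

Given the continuous-time Markov model of occupancy states this module
computes the stationary distribution, forward committor probabilities,
the reactive flux carried by source->sink (e.g. apo -> K1-bound)
trajectories, and the ranked pathways obtained by iterative bottleneck
(widest-path) decomposition of the net-flux network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .kinetics import KineticModel


@dataclass
class FluxDecomposition:
    """Stationary occupancies, committors and ranked reactive pathways."""

    states: list[int]
    labels: list[str]
    pi: np.ndarray
    committor: np.ndarray
    committor_backward: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    paths: list = field(default_factory=list)   # (state tuple, flux)

    def path_labels(self) -> list[tuple[list[str], float]]:
        lab = {s: l for s, l in zip(self.states, self.labels)}
        return [([lab[s] for s in p], f) for p, f in self.paths]


def _active(model: KineticModel) -> np.ndarray:
    return np.flatnonzero(model.visited)


def stationary_distribution(model: KineticModel) -> np.ndarray:
    """Stationary distribution pi solving pi Q = 0, over visited states.

    For a reducible chain a warning is issued and a least-squares stationary
    mixture is returned (any convex combination of the closed classes'
    stationary vectors solves pi Q = 0; the returned one is the minimum-norm
    solution and should be interpreted per communicating class).
    Entries for unvisited states are zero.
    """
    act = _active(model)
    q = model.generator()[np.ix_(act, act)]
    adj = (q > 0).astype(int)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        warnings.warn(f"rate matrix is reducible ({n_comp} communicating "
                      "classes); stationary vector is a per-class mixture")
    # solve pi Q = 0 with sum(pi) = 1 by least squares
    a = np.vstack([q.T, np.ones(len(q))])
    b = np.zeros(len(q) + 1)
    b[-1] = 1.0
    pi_act, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi_act = np.clip(pi_act, 0.0, None)
    pi_act /= pi_act.sum()
    pi = np.zeros(model.n_states)
    pi[act] = pi_act
    return pi


def committor(model: KineticModel, source_states, sink_states) -> np.ndarray:
    """Forward committor q+ (probability of reaching sink before source).

    Solves sum_j Q_ij q+_j = 0 on intermediate states with boundary values
    q+(source) = 0, q+(sink) = 1.  Isolated intermediates (singular rows)
    are flagged NaN with a warning.
    """
    source = set(int(s) for s in np.atleast_1d(source_states))
    sink = set(int(s) for s in np.atleast_1d(sink_states))
    if not source or not sink:
        raise ValueError("source and sink must be non-empty")
    if source & sink:
        raise ValueError("source and sink must be disjoint")
    q = model.generator()
    n = model.n_states
    qplus = np.full(n, np.nan)
    for s in source:
        qplus[s] = 0.0
    for s in sink:
        qplus[s] = 1.0
    inter = [i for i in np.flatnonzero(model.visited)
             if i not in source and i not in sink]
    if inter:
        a = q[np.ix_(inter, inter)]
        rhs = -q[np.ix_(inter, sorted(sink))].sum(axis=1)
        dead = np.abs(a).sum(axis=1) == 0
        if dead.any():
            warnings.warn(f"isolated intermediate states "
                          f"{[inter[i] for i in np.flatnonzero(dead)]}; "
                          "committor undefined there")
            keep = np.flatnonzero(~dead)
            sol = np.full(len(inter), np.nan)
            if len(keep):
                sol[keep] = np.linalg.solve(a[np.ix_(keep, keep)], rhs[keep])
            for i, v in zip(inter, sol):
                qplus[i] = v
        else:
            sol = np.linalg.solve(a, rhs)
            for i, v in zip(inter, sol):
                qplus[i] = float(np.clip(v, 0.0, 1.0))
    return qplus


def backward_committor(model: KineticModel, source_states, sink_states,
                       pi: np.ndarray | None = None) -> np.ndarray:
    """Backward committor q- (probability the process last visited source).

    Computed as the forward committor of the time-reversed chain
    (k~_ij = pi_j k_ji / pi_i) with source and sink swapped.  For models
    satisfying detailed balance this equals 1 - q+.
    """
    if pi is None:
        pi = stationary_distribution(model)
    k = np.where(np.isnan(model.rates), 0.0, model.rates)
    with np.errstate(divide="ignore", invalid="ignore"):
        k_rev = np.where(pi[:, None] > 0, pi[None, :] * k.T / pi[:, None], 0.0)
    reversed_model = KineticModel(model.site_order, k_rev,
                                  model.concentration, model.visited.copy())
    return committor(reversed_model, sink_states, source_states)


def _widest_path(cap: np.ndarray, sources, sinks):
    """Widest (maximum-bottleneck) path through a capacity matrix.

    Dijkstra-style label setting maximizing the minimum edge; ties between
    equal-width relaxations are broken by smaller predecessor index, and the
    scan order over nodes is ascending, so the result is deterministic.
    Returns (path list, bottleneck) or (None, 0).
    """
    n = len(cap)
    width = np.full(n, -1.0)
    prev = np.full(n, -1, dtype=int)
    done = np.zeros(n, dtype=bool)
    for s in sources:
        width[s] = np.inf
    while True:
        cand = np.flatnonzero(~done & (width > 0))
        if len(cand) == 0:
            return None, 0.0
        u = cand[np.argmax(width[cand])]
        if u in sinks:
            path = [int(u)]
            while prev[path[0]] >= 0:
                path.insert(0, int(prev[path[0]]))
            return path, float(width[u])
        done[u] = True
        for v in np.flatnonzero(cap[u] > 0):
            w = min(width[u], cap[u, v])
            if w > width[v] or (w == width[v] and prev[v] > u):
                width[v] = w
                prev[v] = u


def reactive_flux_paths(model: KineticModel, source_states, sink_states,
                        n_paths: int = 2) -> FluxDecomposition:
    """Reactive flux decomposition of the source->sink transition.

    Gross reactive flux f_ij = pi_i q-_i k_ij q+_j (with q- the backward
    committor, equal to 1 - q+ under detailed balance), net flux
    f+_ij = max(f_ij - f_ji, 0); pathways are extracted by repeatedly
    removing the widest (bottleneck) path from the net-flux graph, each
    carrying its bottleneck capacity.  Both gross and net matrices are
    reported.
    """
    source = sorted(set(int(s) for s in np.atleast_1d(source_states)))
    sink = sorted(set(int(s) for s in np.atleast_1d(sink_states)))
    pi = stationary_distribution(model)
    qplus = committor(model, source, sink)
    qminus = backward_committor(model, source, sink, pi=pi)
    k = np.where(np.isnan(model.rates), 0.0, model.rates)
    qp = np.where(np.isnan(qplus), 0.0, qplus)
    qm = np.where(np.isnan(qminus), 0.0, qminus)
    gross = pi[:, None] * qm[:, None] * k * qp[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.clip(gross - gross.T, 0.0, None)
    in_a = np.zeros(model.n_states, dtype=bool)
    in_a[source] = True
    total = float(net[np.ix_(in_a, ~in_a)].sum())

    paths = []
    residual = net.copy()
    if total <= 0:
        warnings.warn("zero reactive flux between source and sink")
    else:
        sinkset = set(sink)
        for _ in range(n_paths):
            path, bottleneck = _widest_path(residual, source, sinkset)
            if path is None or bottleneck <= total * 1e-14:
                break
            for a, b in zip(path[:-1], path[1:]):
                residual[a, b] -= bottleneck
            paths.append((tuple(path), bottleneck))

    act = _active(model).tolist()
    labels = [model.labels()[i] for i in act]
    return FluxDecomposition(act, labels, pi, qplus, qminus, gross, net,
                             total, paths)


def to_dot(decomp: FluxDecomposition, name: str = "flux") -> str:
    """DOT-format text of the net-flux network (node size ~ pi, edge ~ flux)."""
    lines = [f"digraph {name} {{"]
    lab = {s: l for s, l in zip(decomp.states, decomp.labels)}
    for s in decomp.states:
        lines.append(f'  {s} [label="{lab[s]}\\npi={decomp.pi[s]:.3g}"];')
    nz = np.argwhere(decomp.net_flux > 0)
    for i, j in nz:
        lines.append(f'  {i} -> {j} [label="{decomp.net_flux[i, j]:.3g}"];')
    lines.append("}")
    return "\n".join(lines)
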