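"""Gate-opening free-energy profiles and allosteric gating statistics.

Umbrella-sampling windows along the gate-opening reaction coordinate are
combined with the weighted histogram analysis method (WHAM) into a
potential of mean force; the closed-state probability is the Boltzmann mass
below the open/closed boundary (the first local minimum of the bound-state
gate histogram).  The K-type allosteric efficacy

    alpha = K_close(ligand) / K_close(apo),   K_close = p_closed / (1 - p_closed)

quantifies how strongly ligand binding shifts the gate equilibrium.  Block
RMSF statistics and 2-D gate/salt-bridge histograms support the companion
flexibility and coupling analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import DEFAULT_TEMPERATURE, kt
from .occupancy import DistanceTrajectory, OccupancyTrace, state_label


@dataclass
class UmbrellaWindow:
    """One harmonically biased window: U_i(x) = k/2 (x - center)^2."""

    center: float
    force_constant: float        # kJ/mol per (RC unit)^2
    samples: np.ndarray

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.samples).all():
            raise ValueError("window samples must be finite")


@dataclass
class UmbrellaSet:
    """A set of umbrella windows plus thermodynamic metadata."""

    windows: list[UmbrellaWindow]
    temperature: float = DEFAULT_TEMPERATURE
    equilibration_fraction: float = 0.0

    def __post_init__(self):
        if not self.windows:
            raise ValueError("at least one window required")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration fraction in [0, 1)")

    def production_samples(self) -> list[np.ndarray]:
        """Window samples with the leading equilibration fraction dropped."""
        f = self.equilibration_fraction
        return [w.samples[int(len(w.samples) * f):] for w in self.windows]


@dataclass
class PMFProfile:
    """Reconstructed free-energy profile on a reaction-coordinate grid."""

    x: np.ndarray                # bin centers
    g: np.ndarray                # kJ/mol, min-anchored at 0 (inf where unsampled)
    p: np.ndarray                # normalized density (integrates to 1)
    sd_g: np.ndarray | None
    temperature: float
    converged: bool
    n_iterations: int
    window_free_energies: np.ndarray | None = None
    bootstrap_p: np.ndarray | None = None    # (n_boot, n_bins)

    @property
    def bin_width(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass
class GateStats:
    """Closed-state statistics and allosteric efficacy."""

    boundary: float
    p_closed: float
    sd: float
    k_close: float = field(init=False)

    def __post_init__(self):
        self.k_close = self.p_closed / (1.0 - self.p_closed) \
            if 0 < self.p_closed < 1 else np.inf


def _wham_solve(n_im, n_i, log_c, tol, max_iter, f_init=None):
    """Self-consistent WHAM iteration in a numerically safe form.

    n_im: (windows, bins) histogram counts; n_i: samples per window;
    log_c = -beta * bias evaluated at bin centers.  Returns (p, f_kT,
    n_iter, converged) with p unnormalized bin probabilities and f the
    window free energies in kT.
    """
    c = np.exp(log_c)                       # underflow to 0 far from centers
    m_tot = n_im.sum(axis=0)
    f = np.zeros(len(n_i)) if f_init is None else f_init.copy()
    a = np.exp(f)                           # a_i = exp(beta f_i) = 1/Z_i
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = (n_i * a) @ c               # (bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, m_tot / denom, 0.0)
        z = c @ p                           # (windows,)
        f_new = -np.log(z)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
        a = np.exp(f)
    return p, f, it, converged


def wham_profile(uset: UmbrellaSet, n_bins: int = 200, tol: float = 1e-6,
                 max_iter: int = 50000, n_boot: int = 50,
                 n_boot_blocks: int = 20, seed=None,
                 grid_range=None) -> PMFProfile:
    """WHAM reconstruction of the unbiased free-energy profile.

    Iterates the window free energies to self-consistency (``tol`` is the
    maximum change in kT between sweeps).  Per-bin errors come from
    bootstrap resampling of contiguous sample blocks within each window
    (``n_boot`` replicate profiles, warm-started from the converged
    solution).  Raises when adjacent windows share no sampled support and
    flags non-convergence instead of silently returning.
    """
    kt_ = kt(uset.temperature)
    beta = 1.0 / kt_
    samples = uset.production_samples()
    allx = np.concatenate(samples)
    lo, hi = grid_range if grid_range is not None else (allx.min(), allx.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    order = np.argsort([w.center for w in uset.windows])
    n_im = np.vstack([np.histogram(samples[i], bins=edges)[0] for i in order])
    n_i = n_im.sum(axis=1).astype(float)
    win = [uset.windows[i] for i in order]

    # adjacent-window overlap check on sampled support
    occ = [np.flatnonzero(row) for row in n_im]
    for a, b, wa, wb in zip(occ[:-1], occ[1:], win[:-1], win[1:]):
        if len(a) and len(b) and (a.max() < b.min() - 1 or b.max() < a.min() - 1):
            raise ValueError(
                f"no histogram overlap between windows centered at "
                f"{wa.center:.4g} and {wb.center:.4g}")

    bias = np.vstack([0.5 * w.force_constant * (centers - w.center) ** 2
                      for w in win])
    log_c = -beta * bias

    p, f, n_iter, converged = _wham_solve(n_im, n_i, log_c, tol, max_iter)
    if not converged:
        warnings.warn(f"WHAM did not converge within {max_iter} iterations")
    norm = p.sum() * width
    p_norm = p / norm if norm > 0 else p
    with np.errstate(divide="ignore"):
        g = -kt_ * np.log(p_norm)
    g -= g[np.isfinite(g)].min()

    sd_g = None
    boot_p = None
    if n_boot and n_boot > 1:
        rng = np.random.default_rng(seed)
        boot_p = np.empty((n_boot, n_bins))
        for k in range(n_boot):
            rows = []
            for s in [samples[i] for i in order]:
                blocks = np.array_split(s, min(n_boot_blocks, len(s)))
                pick = rng.integers(0, len(blocks), size=len(blocks))
                res = np.concatenate([blocks[j] for j in pick])
                rows.append(np.histogram(res, bins=edges)[0])
            bn = np.vstack(rows)
            bp, _, _, _ = _wham_solve(bn, bn.sum(axis=1).astype(float),
                                      log_c, tol, max_iter, f_init=f)
            bnorm = bp.sum() * width
            boot_p[k] = bp / bnorm if bnorm > 0 else bp
        with np.errstate(divide="ignore"), warnings.catch_warnings():
            # bins unsampled in some replicates give all-NaN slices
            warnings.simplefilter("ignore", RuntimeWarning)
            boot_g = -kt_ * np.log(boot_p)
            boot_g -= np.nanmin(np.where(np.isfinite(boot_g), boot_g, np.nan),
                                axis=1, keepdims=True)
            sd_g = np.nanstd(np.where(np.isfinite(boot_g), boot_g, np.nan),
                             axis=0, ddof=1)

    return PMFProfile(centers, g, p_norm, sd_g, uset.temperature, converged,
                      n_iter, window_free_energies=f * kt_, bootstrap_p=boot_p)


def profile_convergence(block_profiles, threshold: float = 0.80):
    """Histogram-intersection convergence check over the last three blocks.

    Pairwise overlap of two normalized densities is sum_bins min(p, q) * dx,
    a value in [0, 1]; the run passes when every pair among the last three
    block densities overlaps by at least ``threshold``.  Profiles on
    different grids are regridded (linear interpolation) onto the last
    block's grid.  Returns (min_overlap, passed, pairwise dict).
    """
    profiles = list(block_profiles)
    if len(profiles) < 3:
        raise ValueError("need >= 3 block profiles")
    last3 = profiles[-3:]
    ref = last3[-1]
    dens = []
    for prof in last3:
        if len(prof.x) != len(ref.x) or not np.allclose(prof.x, ref.x):
            p = np.interp(ref.x, prof.x, prof.p, left=0.0, right=0.0)
            norm = p.sum() * ref.bin_width
            p = p / norm if norm > 0 else p
        else:
            p = prof.p
        dens.append(p)
    overlaps = {}
    for i in range(3):
        for j in range(i + 1, 3):
            ov = float(np.minimum(dens[i], dens[j]).sum() * ref.bin_width)
            overlaps[(i, j)] = ov
    min_ov = min(overlaps.values())
    return min_ov, min_ov >= threshold, overlaps


def find_gate_boundary(counts, centers, smoothing_width: float = 2.0) -> float:
    """Open/closed boundary: first interior local minimum of the histogram.

    Scans from small distances upward after optional Gaussian smoothing
    (``smoothing_width`` in bins; 0 disables smoothing) and returns the
    center of the first interior bin strictly lower than both neighbors.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if len(counts) < 3:
        raise ValueError("histogram needs >= 3 bins")
    smooth = gaussian_filter1d(counts, smoothing_width) if smoothing_width > 0 \
        else counts
    interior = (smooth[1:-1] < smooth[:-2]) & (smooth[1:-1] < smooth[2:])
    idx = np.flatnonzero(interior)
    if len(idx) == 0:
        raise ValueError("no interior local minimum found; the histogram may "
                         "be monotone -- try a larger smoothing width")
    return float(centers[idx[0] + 1])


def closed_probability(profile_or_trace, boundary: float, seed=None,
                       n_boot: int = 1000):
    """Probability of the gate being closed (coordinate below ``boundary``).

    PMF mode (a :class:`PMFProfile`): integral of the normalized density
    below the boundary, with SD from the profile's bootstrap replicates.
    Trace mode (one array or a list of per-monomer arrays): fraction of
    frames below the boundary, with SD from monomer bootstrap when several
    monomers are given.  Returns a :class:`GateStats`.
    """
    if isinstance(profile_or_trace, PMFProfile):
        prof = profile_or_trace
        if not (prof.x[0] <= boundary <= prof.x[-1]):
            raise ValueError("boundary outside the profile grid")
        p_cl = _integrate_below(prof.x, prof.p, prof.bin_width, boundary)
        sd = 0.0
        if prof.bootstrap_p is not None:
            vals = np.array([_integrate_below(prof.x, bp, prof.bin_width,
                                              boundary)
                             for bp in prof.bootstrap_p])
            sd = float(vals.std(ddof=1))
        return GateStats(boundary, float(p_cl), sd)

    if isinstance(profile_or_trace, np.ndarray):
        monomers = [profile_or_trace]
    else:
        monomers = [np.asarray(m, dtype=float) for m in profile_or_trace]
    fractions = np.array([(m < boundary).mean() for m in monomers])
    weights = np.array([len(m) for m in monomers], dtype=float)
    p_cl = float(np.average(fractions, weights=weights))
    sd = 0.0
    if len(monomers) > 1:
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, len(monomers), size=(n_boot, len(monomers)))
        vals = np.array([np.average(fractions[p], weights=weights[p])
                         for p in picks])
        sd = float(vals.std(ddof=1))
    return GateStats(boundary, p_cl, sd)


def _integrate_below(x, p, width, boundary):
    mass = p[x + width / 2 <= boundary].sum() * width
    straddle = np.flatnonzero((x - width / 2 < boundary) & (x + width / 2 > boundary))
    for i in straddle:
        mass += p[i] * (boundary - (x[i] - width / 2))
    return mass


def conditional_gate_histograms(traj: DistanceTrajectory, occ: OccupancyTrace,
                                bins=60):
    """Gate-distance histograms conditioned on the occupancy state.

    Returns ``{state label: (density, edges, n_frames)}`` with one
    normalized histogram per occupancy condition; conditions without frames
    are omitted (noted in a warning).  The edges are shared so histograms
    are comparable and recombine (weighted by state occupancy) into the
    total histogram.
    """
    if traj.gate is None:
        raise ValueError("trajectory carries no gate-distance series")
    if len(traj.gate) != occ.n_frames:
        raise ValueError("gate series and occupancy trace are not aligned")
    edges = np.histogram_bin_edges(traj.gate, bins=bins)
    out = {}
    for code in np.unique(occ.states):
        sel = traj.gate[occ.states == code]
        dens, _ = np.histogram(sel, bins=edges, density=True)
        out[state_label(int(code), occ.site_order)] = (dens, edges, len(sel))
    missing = 2 ** len(occ.site_order) - len(out)
    if missing:
        warnings.warn(f"{missing} occupancy conditions had no frames and "
                      "were omitted")
    return out


def allosteric_efficacy(p_closed_apo: float, p_closed_bound: float,
                        boot_apo=None, boot_bound=None, seed=None):
    """K-type allosteric efficacy alpha with bootstrap SD.

    alpha = [p_b / (1 - p_b)] / [p_a / (1 - p_a)], the ratio of the gate
    closure equilibrium constants with and without the ligand.  When
    bootstrap samples of the two probabilities are supplied they are paired
    at random (the two conditions come from independent simulations) to
    propagate the uncertainty.  Returns (alpha, sd).
    """
    for p in (p_closed_apo, p_closed_bound):
        if not 0 < p < 1:
            raise ValueError(f"closed probability {p} is 0 or 1; the odds "
                             "ratio is undefined/infinite")
    odds = lambda p: p / (1.0 - p)
    alpha = odds(p_closed_bound) / odds(p_closed_apo)
    sd = 0.0
    if boot_apo is not None and boot_bound is not None:
        boot_apo = np.asarray(boot_apo, dtype=float)
        boot_bound = np.asarray(boot_bound, dtype=float)
        rng = np.random.default_rng(seed)
        n = max(len(boot_apo), len(boot_bound))
        a = boot_apo[rng.integers(0, len(boot_apo), size=n)]
        b = boot_bound[rng.integers(0, len(boot_bound), size=n)]
        ok = (a > 0) & (a < 1) & (b > 0) & (b < 1)
        vals = odds(b[ok]) / odds(a[ok])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(alpha), sd


def rmsf_blocks(coords: np.ndarray, n_blocks: int = 10):
    """Per-residue RMSF as mean +- SD over contiguous trajectory blocks.

    ``coords`` has shape (n_frames, n_residues, 3) (pre-aligned positions;
    no superposition fitting is applied).  Each block's RMSF is the root
    mean squared deviation from the block-mean position.  Returns
    (mean, sd) arrays of length n_residues.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[:, :, None]
    if coords.shape[0] < n_blocks:
        raise ValueError("fewer frames than blocks")
    vals = []
    for block in np.array_split(coords, n_blocks, axis=0):
        dev = block - block.mean(axis=0, keepdims=True)
        vals.append(np.sqrt((dev ** 2).sum(axis=2).mean(axis=0)))
    vals = np.vstack(vals)
    return vals.mean(axis=0), vals.std(axis=0, ddof=1)


def hist2d_gate_saltbridge(gate: np.ndarray, pair: np.ndarray,
                           thresholds: tuple[float, float], bins=50):
    """2-D gate vs salt-bridge distance density with quadrant occupancies.

    ``thresholds`` = (gate threshold for closed, pair threshold for a
    formed bridge).  Returns (density, gate_edges, pair_edges, quadrants)
    where quadrants maps e.g. 'closed/formed' to its probability mass; the
    four masses sum to 1.
    """
    gate = np.asarray(gate, dtype=float)
    pair = np.asarray(pair, dtype=float)
    if len(gate) != len(pair):
        raise ValueError("series must have equal length")
    if len(gate) == 0:
        raise ValueError("empty series")
    h, ge, pe = np.histogram2d(gate, pair, bins=bins, density=True)
    g_thr, p_thr = thresholds
    closed = gate < g_thr
    formed = pair < p_thr
    n = len(gate)
    quadrants = {
        "closed/formed": float((closed & formed).sum() / n),
        "closed/broken": float((closed & ~formed).sum() / n),
        "open/formed": float((~closed & formed).sum() / n),
        "open/broken": float((~closed & ~formed).sum() / n),
    }
    return h, ge, pe, quadrants
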