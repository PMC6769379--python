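"""Non-parametric analysis of microscale thermophoresis binding curves.

MST reports a fluorescence change after a temperature jump as a function of
ligand concentration.  Because the curves often do not saturate, parametric
Hill fits are unreliable; instead the binding curve is estimated by
Nadaraya-Watson (local-constant) kernel regression on the log10
concentration axis, with percentile confidence bands from bootstrap
resampling of whole replicate curves, and differences between conditions
are judged by confidence-band overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class MSTCurveSet:
    """Replicate normalized binding curves on a common concentration grid.

    Each curve is normalized to 1 at the lowest concentration (the
    per-curve anchor applied after the per-trace temperature-jump
    normalization).
    """

    concentrations: np.ndarray   # mM, strictly increasing
    curves: np.ndarray           # (n_curves, n_concentrations)
    reference_time: float = 0.4  # s after the temperature jump

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.curves.shape[1] != len(self.concentrations):
            raise ValueError("curve length does not match concentration grid")

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def log_conc(self) -> np.ndarray:
        return np.log10(self.concentrations)


@dataclass
class MSTFit:
    """Kernel-regression fit with bootstrap confidence bands."""

    grid: np.ndarray             # log10 concentration
    mean: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    bandwidth: float
    n_boot: int
    level: float


def normalize_mst(time: np.ndarray, traces: np.ndarray,
                  concentrations: np.ndarray, reference_time: float = 0.4,
                  steady_fraction: float = 0.2) -> MSTCurveSet:
    """Normalize raw fluorescence time traces into one binding curve.

    ``traces`` has shape (n_concentrations, n_times).  For each trace the
    steady-state fluorescence (mean over the trailing ``steady_fraction``
    of the trace) is divided by the value at ``reference_time`` after the
    jump (interpolated); the curve is then anchored to 1 at the lowest
    concentration.  Multiple replicate runs are normalized one call each
    and stacked into an :class:`MSTCurveSet`.
    """
    time = np.asarray(time, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if not (time.min() <= reference_time <= time.max()):
        raise ValueError(f"reference time {reference_time}s outside trace")
    n_tail = max(1, int(len(time) * steady_fraction))
    ref = np.array([np.interp(reference_time, time, tr) for tr in traces])
    if np.any(ref == 0):
        raise ValueError("zero fluorescence at the reference time")
    steady = traces[:, -n_tail:].mean(axis=1)
    curve = steady / ref
    curve = curve / curve[0]
    return MSTCurveSet(np.asarray(concentrations, dtype=float), curve[None, :])


def stack_curves(curve_sets) -> MSTCurveSet:
    """Stack independently normalized replicate curves into one set."""
    sets = list(curve_sets)
    base = sets[0]
    for s in sets[1:]:
        if not np.allclose(s.concentrations, base.concentrations):
            raise ValueError("replicates on different concentration grids")
    return MSTCurveSet(base.concentrations,
                       np.vstack([s.curves for s in sets]),
                       base.reference_time)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb on the design points."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        return 1.0
    return 0.9 * scale * n ** (-1 / 5)


def nw_estimate(x_data, y_data, grid, bandwidth):
    """Plain Nadaraya-Watson local-constant estimate with Gaussian kernel."""
    x_data = np.asarray(x_data, dtype=float)
    y_data = np.asarray(y_data, dtype=float)
    w = np.exp(-0.5 * ((np.asarray(grid)[:, None] - x_data[None, :])
                       / bandwidth) ** 2)
    return (w @ y_data) / w.sum(axis=1)


def nw_fit_with_ci(curves: MSTCurveSet, bandwidth="auto", n_boot: int = 10000,
                   level: float = 0.99, seed=None, grid=None,
                   n_grid: int = 100) -> MSTFit:
    """Nadaraya-Watson fit of the binding curve with bootstrap bands.

    Regression runs on the log10-concentration axis (serial dilutions are
    geometric).  ``bandwidth='auto'`` applies Silverman's rule to the
    design points.  Whole replicate curves are the bootstrap unit;
    percentile bands at ``level`` are returned.  With a single curve the
    fit is returned without bands (flagged by a warning).
    """
    if len(curves.concentrations) < 3:
        raise ValueError("need >= 3 concentrations")
    x = curves.log_conc
    if bandwidth == "auto":
        h = silverman_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)

    x_all = np.tile(x, curves.n_curves)
    y_all = curves.curves.ravel()
    mean = nw_estimate(x_all, y_all, grid, h)

    lower = upper = None
    if curves.n_curves < 2:
        warnings.warn("single curve: confidence bands unavailable")
    elif n_boot > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(grid)))
        for k in range(n_boot):
            pick = rng.integers(0, curves.n_curves, size=curves.n_curves)
            y = curves.curves[pick].ravel()
            boots[k] = nw_estimate(x_all, y, grid, h)
        q = (1.0 - level) / 2
        lower = np.percentile(boots, 100 * q, axis=0)
        upper = np.percentile(boots, 100 * (1 - q), axis=0)
        # percentile bands from finite resamples can sit on one side of the
        # point fit; clip so lower <= mean <= upper holds exactly
        lower = np.minimum(lower, mean)
        upper = np.maximum(upper, mean)
    return MSTFit(grid, mean, lower, upper, h, n_boot, level)


def ci_overlap_test(fit_a: MSTFit, fit_b: MSTFit,
                    min_run_fraction: float = 0.10):
    """Significance by confidence-band separation.

    Fits are regridded onto the shared concentration range; a grid point is
    flagged when the two intervals are disjoint.  The overall verdict is
    'significant' when a contiguous run of flagged points spans at least
    ``min_run_fraction`` of the grid (a single-point separation is treated
    as a multiplicity artifact).  Returns (flags, significant, grid).
    """
    for f in (fit_a, fit_b):
        if f.lower is None or f.upper is None:
            raise ValueError("both fits need confidence bands")
    lo = max(fit_a.grid.min(), fit_b.grid.min())
    hi = min(fit_a.grid.max(), fit_b.grid.max())
    if lo >= hi:
        raise ValueError("fits cover disjoint concentration ranges")
    n = max(len(fit_a.grid), len(fit_b.grid))
    grid = np.linspace(lo, hi, n)
    la = np.interp(grid, fit_a.grid, fit_a.lower)
    ua = np.interp(grid, fit_a.grid, fit_a.upper)
    lb = np.interp(grid, fit_b.grid, fit_b.lower)
    ub = np.interp(grid, fit_b.grid, fit_b.upper)
    flags = (ua < lb) | (ub < la)

    run = best = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    significant = best >= max(1, int(np.ceil(min_run_fraction * n)))
    return flags, bool(significant), grid
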