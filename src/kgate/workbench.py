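"""Shared I/O, bootstrap utilities and the end-to-end pipeline driver.

File formats are plain delimited text: xvg-style comment lines starting
with '#' or '@' are skipped, trace files carry a one-line JSON header
comment with dt, units and the generating seed, and reports are JSON/CSV.
All randomness flows from explicit seeds in the configuration; there is no
hidden global state, so a pipeline rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alchemy, electromap, kinetics, mstfit, occupancy, pathflux, \
    pmfgate, synthgen

# ---------------------------------------------------------------------------
# delimited-text I/O


def read_timeseries_table(path, column_map: dict | None = None,
                          sep=None) -> pd.DataFrame:
    """Read a delimited time-series table, skipping #/@ comment lines.

    ``column_map`` renames file columns to canonical names (e.g.
    {'t': 'time', 'd': 'K1'}); if a 'time' column results, it must be
    non-decreasing.  The delimiter is sniffed (whitespace or comma) unless
    given.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith(("#", "@"))]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    if sep is None:
        sep = "," if "," in lines[0] else r"\s+"
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep,
                     float_precision="round_trip")
    if column_map:
        missing = set(column_map) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df.rename(columns=column_map)
    if "time" in df.columns and np.any(np.diff(df["time"].to_numpy()) < 0):
        raise ValueError(f"{path}: time column is not monotone")
    return df


def write_trace_csv(trace: "synthgen.BindingTrace", path) -> None:
    """Write a binding trace as CSV with a JSON header comment.

    A sibling ``<stem>.truth.csv`` holds the hidden ground-truth state
    path for validation.
    """
    path = Path(path)
    traj = trace.trajectory
    header = {
        "dt_us": traj.dt,
        "units": {"distance": "A", "time": "us"},
        "concentration_M": traj.concentration,
        "monomer": traj.monomer_id,
        "sites": list(traj.sites),
    }
    df = pd.DataFrame({"time": np.arange(traj.n_frames) * traj.dt})
    for s in traj.sites:
        df[s] = traj.distances[s]
    if traj.gate is not None:
        df["gate"] = traj.gate
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    truth = pd.DataFrame({"time": df["time"], "state": trace.hidden_states})
    with open(path.with_suffix(".truth.csv"), "w") as fh:
        fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        truth.to_csv(fh, index=False, float_format="%.17g")


def read_trace_csv(path) -> occupancy.DistanceTrajectory:
    """Read a trace CSV written by :func:`write_trace_csv`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header = json.loads(first.lstrip("#").strip()) if first.startswith("#") \
        else {}
    df = read_timeseries_table(path)
    sites = header.get("sites") or [c for c in df.columns
                                    if c not in ("time", "gate")]
    return occupancy.DistanceTrajectory(
        header.get("monomer", path.stem),
        header.get("dt_us", float(df["time"].iloc[1] - df["time"].iloc[0])),
        {s: df[s].to_numpy() for s in sites},
        gate=df["gate"].to_numpy() if "gate" in df.columns else None,
        concentration=header.get("concentration_M", 1.0))


# ---------------------------------------------------------------------------
# generic bootstrap


@dataclass
class BootstrapResult:
    mean: float
    sd: float
    ci: tuple[float, float]
    failed_fraction: float
    samples: np.ndarray


def bootstrap_statistic(samples, statistic, n_boot: int = 1000, seed=None,
                        ) -> BootstrapResult:
    """Bootstrap a statistic over independent sample units.

    ``samples`` is a sequence of units (scalars, arrays, traces, ...);
    units are resampled with replacement and ``statistic`` is evaluated on
    each resampled list.  Deterministic given the seed.  Aborts when the
    statistic fails on more than half of the resamples.
    """
    units = list(samples)
    if not units:
        raise ValueError("need >= 1 sample unit")
    rng = np.random.default_rng(seed)
    vals, failed = [], 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(units), size=len(units))
        try:
            vals.append(float(statistic([units[i] for i in pick])))
        except Exception:
            failed += 1
    if failed > 0.5 * n_boot:
        raise RuntimeError(f"statistic failed on {failed}/{n_boot} resamples")
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    ci = tuple(np.percentile(vals, [2.5, 97.5])) if len(vals) > 1 else \
        (float(vals[0]), float(vals[0]))
    return BootstrapResult(float(vals.mean()), sd, ci, failed / n_boot, vals)


# ---------------------------------------------------------------------------
# pipeline driver


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _digest(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_simulate_binding(params, ctx, outdir):
    spec = synthgen.RateSpec.two_state(
        site=params.get("site", "K1"),
        kd_mm=params.get("kd_mm", 8.0),
        k_off=params.get("k_off", 0.1),
        concentration=params.get("concentration", 1.0))
    traces = synthgen.gen_binding_traj(
        spec, duration=params["duration_us"], dt=params["dt_us"],
        n_monomers=params.get("n_monomers", 4), seed=params["seed"])
    ctx["binding_traces"] = traces
    ctx["binding_spec"] = spec
    return {"n_monomers": len(traces),
            "n_frames": traces[0].trajectory.n_frames,
            "true_kd_mm": params.get("kd_mm", 8.0)}


def _stage_kinetics(params, ctx, outdir):
    traces = ctx["binding_traces"]
    site = params.get("site", "K1")
    occs = [occupancy.discretize_trajectory(t.trajectory,
                                            params.get("threshold"))
            for t in traces]
    census = occupancy.transition_census(occs,
                                         min_dwell=params.get("min_dwell", 0))
    model = kinetics.estimate_rate_matrix(census)
    est = kinetics.dissociation_constants(
        model, site, n_boot=params.get("n_boot", 1000), seed=params["seed"])
    ctx["kinetic_model"] = model
    report = {"site": site, "kd_mm": est.kd_mm, "sd_mm": est.sd_mm,
              "ci_mm": list(est.ci), "on_rate_2nd_per_us_M": est.on_rate_2nd,
              "off_rate_per_us": est.off_rate,
              "n_on": est.n_on, "n_off": est.n_off}
    _write_json(outdir / "kd_report.json", report)
    pd.DataFrame([report]).to_csv(outdir / "kd_table.csv", index=False)
    return report


def _stage_tpt(params, ctx, outdir):
    model = ctx["kinetic_model"]
    so = model.site_order
    src = [occupancy.label_to_state(s, so) for s in params.get("source", ["apo"])]
    snk = [occupancy.label_to_state(s, so) for s in params["sink"]]
    dec = pathflux.reactive_flux_paths(model, src, snk,
                                       n_paths=params.get("n_paths", 2))
    report = {"total_flux": dec.total_flux,
              "paths": [{"states": list(p), "flux": f}
                        for p, f in dec.paths]}
    _write_json(outdir / "flux_report.json", report)
    (outdir / "flux_graph.dot").write_text(pathflux.to_dot(dec))
    return report


def _stage_cgi(params, ctx, outdir):
    works = synthgen.gen_work_samples(
        dg=params["dg"], sigma=params.get("sigma", 4.0),
        n_forward=params.get("n", 250), n_reverse=params.get("n", 250),
        temperature=params.get("temperature", 310.0), seed=params["seed"])
    est = alchemy.cgi_estimate(works, n_boot=params.get("n_boot", 1000),
                               seed=params["seed"] + 1)
    report = {"dg_kj_mol": est.dg, "sd": est.sd, "method": est.method,
              "converged": est.converged, "true_dg": params["dg"]}
    _write_json(outdir / "cgi_report.json", report)
    return report


def _stage_gating(params, ctx, outdir):
    report = {}
    boots = {}
    for cond in ("apo", "bound"):
        pmf = synthgen.calibrate_double_well(params[f"closed_{cond}"])
        centers = np.linspace(pmf.domain[0], pmf.domain[1],
                              params.get("n_windows", 44))
        uset = synthgen.gen_umbrella_set(
            pmf, centers, params.get("force_constant", 1000.0),
            params.get("n_per_window", 2000), seed=params["seed"])
        prof = pmfgate.wham_profile(uset, n_boot=params.get("n_boot", 30),
                                    seed=params["seed"] + 1)
        hist = prof.p
        boundary = pmfgate.find_gate_boundary(hist, prof.x)
        stats = pmfgate.closed_probability(prof, boundary)
        report[cond] = {"p_closed": stats.p_closed, "sd": stats.sd,
                        "boundary": boundary,
                        "true_p_closed": params[f"closed_{cond}"]}
        boots[cond] = np.array(
            [pmfgate._integrate_below(prof.x, bp, prof.bin_width, boundary)
             for bp in prof.bootstrap_p]) if prof.bootstrap_p is not None else None
    alpha, sd = pmfgate.allosteric_efficacy(
        report["apo"]["p_closed"], report["bound"]["p_closed"],
        boots["apo"], boots["bound"], seed=params["seed"] + 2)
    report["alpha"] = {"value": alpha, "sd": sd}
    _write_json(outdir / "gating_report.json", report)
    return report


def _stage_charge(params, ctx, outdir):
    fits = {}
    for i, st in enumerate(params["states"]):
        series = synthgen.gen_capacitor_series(
            q_p0=st["q_p0"], c0=params.get("c0", 0.05),
            q_sol_values=params.get("q_sol", [-12, -10, -8, -6]),
            noise_sd=params.get("noise_sd", 5.0),
            n_replicates=params.get("n_replicates", 5),
            seed=params["seed"] + i, state=st["name"])
        fits[st["name"]] = electromap.fit_capacitor_response(
            series, n_boot=params.get("n_boot", 1000),
            seed=params["seed"] + 100 + i)
    disp = electromap.displacement_matrix(fits)
    report = {
        "fits": {k: {"q_p0": f.q_p0, "sd": f.sd_q_p0, "c0": f.c0}
                 for k, f in fits.items()},
        "displacements": {f"{a}->{b}": {"dq_e0": d, "sd": s}
                          for (a, b), (d, s) in disp.items()},
    }
    _write_json(outdir / "charge_report.json", report)
    return report


def _stage_mst(params, ctx, outdir):
    conc = np.asarray(params.get("concentrations",
                                 (2 ** np.arange(12) * 0.5).tolist()))
    fits = {}
    for i, cond in enumerate(params["conditions"]):
        curves = synthgen.gen_mst_curves(
            kd=cond["kd_mm"], amplitude=params.get("amplitude", -0.2),
            baseline=1.0, concentrations=conc,
            noise_sd=params.get("noise_sd", 0.005),
            n_curves=params.get("n_curves", 4), seed=params["seed"] + i)
        fits[cond["name"]] = mstfit.nw_fit_with_ci(
            curves, n_boot=params.get("n_boot", 2000),
            seed=params["seed"] + 100 + i)
    names = list(fits)
    report = {"bandwidths": {k: fits[k].bandwidth for k in names}}
    if len(names) >= 2:
        _, sig, _ = mstfit.ci_overlap_test(fits[names[0]], fits[names[1]])
        report["significant_difference"] = sig
    for k, f in fits.items():
        pd.DataFrame({"log10_conc": f.grid, "mean": f.mean,
                      "lower": f.lower, "upper": f.upper}).to_csv(
            outdir / f"mst_fit_{k}.csv", index=False)
    _write_json(outdir / "mst_report.json", report)
    return report


_STAGES = {
    "simulate_binding": (_stage_simulate_binding, []),
    "kinetics": (_stage_kinetics, ["binding_traces"]),
    "tpt": (_stage_tpt, ["kinetic_model"]),
    "cgi": (_stage_cgi, []),
    "gating": (_stage_gating, []),
    "charge": (_stage_charge, []),
    "mst": (_stage_mst, []),
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, outdir=None) -> dict:
    """Execute configured stages in order and write a manifest.

    ``config`` is a mapping (or YAML path) with a ``stages`` list; every
    stochastic stage must carry an explicit ``seed``.  A stage failure
    aborts only its dependents; the manifest records parameters, digests
    and per-stage status.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir if outdir is not None
                  else config.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    manifest = {"config_digest": _digest(config), "stages": []}
    for entry in config.get("stages", []):
        name = entry["stage"]
        params = {k: v for k, v in entry.items() if k != "stage"}
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        fn, needs = _STAGES[name]
        record = {"stage": name, "params": params}
        missing = [n for n in needs if n not in ctx]
        if missing:
            record["status"] = f"skipped (missing upstream: {missing})"
        else:
            if "seed" not in params and name != "tpt":
                raise ValueError(f"stage {name!r} needs an explicit seed")
            try:
                record["result"] = fn(params, ctx, outdir)
                record["status"] = "ok"
            except Exception as exc:  # dependents are skipped, not the run
                warnings.warn(f"stage {name} failed: {exc}")
                record["status"] = f"failed: {exc}"
        manifest["stages"].append(record)
    _write_json(outdir / "manifest.json", manifest)
    return manifest
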