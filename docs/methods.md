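# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter when reading results.

## Units and constants

Canonical internal units: Å (ion–site and gate distances), nm (gate
reaction coordinate), µs (trajectory time), ns (Langevin time), mM
(reported K_D; bulk concentration in M), kJ/mol, K, e₀, mV.  The default
temperature is 310 K (kT = 2.577 kJ/mol).

## Occupancy and kinetics

A site is *bound* in a frame when the ion–site distance is at or below
the threshold; the default 3.5 Å is the midpoint of the commonly used
3.3–3.65 Å discretization range, overridable per site.  The tie (distance
exactly at threshold) counts as bound — an arbitrary but deterministic
rule.  Sites map to bits of a compound state (K1→bit 0, … by sorted site
name), giving the 8-state (three sites) or 16-state (four sites) tables.
When several ions are present a site is bound if *any* ion is within
threshold; ion identity is not tracked, matching occupancy-based
analysis of closest-ion distances.

Dwell time is frame-based (each frame contributes dt to its state), so
the census conserves total duration exactly.  `min_dwell` (default 0, no
flicker filter) merges runs shorter than the given number of frames into
the longer flanking run (earlier run on ties).  Multi-site flips between
adjacent frames are counted as the single observed compound transition.

Rates are the maximum-likelihood estimator `k_ij = N_ij / t_i`.  Site
on/off rates pool all compound states by the site's bit (one K_D per
site, not per compound state); the second-order on rate divides the
pseudo-first-order rate by the bulk concentration, and
`K_D = k_off / k_on⁽²⁾`, reported in mM.  Uncertainty is a 1,000-sample
bootstrap treating complete monomer trajectories as the independent
unit.  For a site whose unbinding was never observed,
`kd_upper_bound` posits exactly one escape event in the accumulated
bound dwell time (`k_out^max = 1/t_bound`) and scales a reference site's
K_D by `k_out^max / k_in^obs`, where `k_in^obs` is the observed
reference→target relocation rate.  The combining formula is a
detailed-balance construction; the function returns an explicit
assumption log, and the bound should be read as an order-of-magnitude
statement, not an estimate.

## Transition-path analysis

The estimated rate matrix defines a CTMC generator Q.  The stationary
distribution solves πQ = 0 (least squares with Σπ = 1; reducible chains
produce a warning and a per-class mixture).  Forward committors solve the
standard linear system with 0/1 boundary conditions; backward committors
are forward committors of the time-reversed chain
(`k̃_ij = π_j k_ji / π_i`).  The gross reactive flux is
`f_ij = π_i q⁻_i k_ij q⁺_j`; using q⁻ rather than 1−q⁺ keeps flux exactly
conserved at intermediate states for non-reversible matrices (the two
coincide under detailed balance).  Net flux is `max(f−fᵀ, 0)`; pathways
are extracted by repeatedly removing the widest (maximum-bottleneck) path
— ties broken by smaller state index — each carrying its bottleneck
capacity.  Both gross and net matrices are reported since flux analyses
in the literature are not always explicit about which they rank.
Committors use dense solves; the state spaces here are ≤ 16.

## Crooks Gaussian intersection

Forward and negated-reverse work samples are fitted by Gaussians (sample
mean, unbiased variance); ΔG is the density-intersection root between the
means.  When `|σ_f² − σ_r²| < 10⁻⁶·max(σ²)` the quadratic is numerically
unstable and the equal-variance midpoint `(μ_f+μ_r)/2` is used; if no
root lies between the means (pathological overlap) the midpoint is
returned with a `midpoint-fallback` flag and a warning.  The estimator is
antisymmetric under direction swap and, for the Gaussian Crooks family,
consistent with the closed form `ΔG = μ_f − σ²/2kT`.  Bootstrap
resamples works within each direction; block convergence splits each
direction chronologically in two and requires the block estimates to
differ by <10% (an absolute 1 kJ/mol criterion applies when the mean is
near zero, where a relative test is meaningless).  ΔΔG combines two legs
by quadrature by default; a paired mode differencing bootstrap samples is
available when the legs share correlated inputs.  A head-drop fraction
supports discarding equilibration from real work series (default 0 for
synthetic data).

## WHAM gating profiles

Windows biased by `k/2 (x−c)²` are histogrammed on a common grid (200
bins default) and the window free energies iterated to self-consistency;
the tolerance is 10⁻⁶ kT on the maximum change per sweep (with a 50,000
iteration cap and an explicit non-converged flag).  Unsampled gaps
between adjacent windows raise an error naming the gap.  Per-bin errors
and the closed-probability SE come from bootstrap over contiguous sample
blocks within each window (50 replicate profiles by default, warm-started
from the converged solution).

The open/closed boundary is the first interior local minimum of the
(bound-state) gate histogram scanning from small distances, after a
Gaussian smoothing of 2 bins (width 0 gives the raw-histogram minimum).
Closed probability integrates the normalized density below the boundary
(PMF mode) or counts frames below it (trace mode, monomer bootstrap).
Block-profile convergence uses the histogram-intersection overlap
`Σ min(p,q)·dx` of the last three blocks with a 0.80 threshold; the
overlap metric is the simplest normalized choice where the criterion
itself does not fix one.

The allosteric efficacy is the odds ratio
`α = [p_b/(1−p_b)] / [p_a/(1−p_a)]`; apo and bound bootstrap samples are
paired at random because the two conditions come from independent
simulations.  RMSF uses deviations from the block mean without
superposition fitting (inputs are assumed pre-aligned), reported as
mean ± SD over 10 contiguous blocks.

## Charge displacement

Unweighted ordinary least squares on `V = a·q_sol + b` gives `C0 = 1/a`
and `q_p0 = b/a`; a non-positive slope is rejected as unphysical.  The
bootstrap resamples whole replicate trajectories at fixed charge
imbalance, never individual records.  Displacements difference `q_p0`
between states with quadrature SDs.

## MST kernel fits

Curves are normalized per trace to the fluorescence 0.4 s after the
temperature jump and anchored to 1 at the lowest concentration.
Regression is local-constant (Nadaraya–Watson) with a Gaussian kernel on
the log10-concentration axis, because serial dilutions are geometric;
"automatic" bandwidth is Silverman's rule on the design points (the
standard default where no rule is specified, recorded in the output).
Bands are percentile intervals over bootstrap resamples of whole curves.
Two conditions differ *significantly* when their bands are disjoint over
a contiguous run covering ≥10% of the shared grid — a single-point
separation is treated as a multiplicity artifact; the fraction is
configurable.  Measured calibration: with 20 replicate curves the
nominal 99% band contains the smoothed true curve at ≥95% of grid points
in ~93% of repeated experiments, and undercovers substantially with ≤5
curves — a known property of percentile bootstrap at few replicates that
should be kept in mind when reading band-overlap verdicts from small
replicate sets.

## Synthetic generators

`gen_binding_traj` samples the hidden occupancy path *exactly*
(event-driven Gillespie), reads it out on the frame grid and emits
distances: bound sites draw iid from Normal(3.0 Å, 0.15 Å) truncated
below the threshold; unbound sites follow an Ornstein–Uhlenbeck excursion
process (mean 15 Å, SD 5 Å, correlation time 0.05 µs) reflected at
threshold + 0.5 Å.  The clean separation means discretization recovers
the hidden path exactly up to grid effects, enabling confusion-matrix
tests; the hidden path and jump chain are always returned.  What is *not*
emulated: emission noise straddling the threshold (real distance traces
flicker near it), multi-ion competition within one site, and correlated
noise between sites — so passing recovery tests demonstrates estimator
correctness, not robustness to discretization ambiguity.  Frame read-out
misses excursions shorter than dt (fraction ≈ dt/2τ of dwells); reference
studies choose dt ≤ 1/40 of the shortest mean dwell, keeping that bias
near 1%.

`gen_work_samples` draws forward works from
Normal(ΔG + σ²/2kT, σ²) and negated reverse works from
Normal(ΔG − σ²/2kT, σ²), the unique Gaussian pair with common variance
satisfying the fluctuation relation exactly.  `gen_umbrella_set` draws
iid samples from the exact biased Boltzmann density by inverse-CDF on a
dense grid — unlike MD samples these are uncorrelated, so WHAM error bars
on synthetic data are optimistic relative to real trajectories.
`gen_langevin_trace` integrates overdamped dynamics (Euler–Maruyama,
reflecting walls); dt must keep βD|G′|dt small — in practice
dt ≲ 0.1·kT/(D·max|G″|).  Capacitor and MST generators add iid Gaussian
noise to the exact linear/hyperbolic laws.

The analytic gate profile is a quartic double well
`G = h((x/w)²−1)² + t·x` (default wells near ±0.6 nm, 15 kJ/mol barrier
on a [−1.1, 1.1] nm domain — a barrier a few kT high with clearly
separated basins, as gate-opening profiles show).
`calibrate_double_well` root-finds the tilt so the Boltzmann mass of the
closed (small-x) basin, delimited by the interior barrier top, equals a
requested probability; calibration targets define the study conditions.

## Reference study conditions

`kgate.studies` fixes the desk-scale problem sizes used by the validation
suite and the acceptance script: K_D recovery with 20 monomers and ~500
expected binding events (k_off = 0.1 /µs, dt = 2 ns in the high-affinity
regime; k_off = 0.3 /µs, dt = 10 ns in the low-affinity one); CGI and
ΔΔG with 250 works per direction at σ = 4 kJ/mol and 310 K; gating with
44 windows at k = 1000 kJ/mol/nm² and 9000 samples per window.  At these
sizes the estimators carry relative SEs of roughly 6% (K_D), 1% (ΔG) and
5% (closed probability of a rarely visited basin), which the bootstrap
intervals reproduce; recovery is checked against those intervals rather
than against fixed percentages.

## Known limitations

* The K_D upper-bound arithmetic is a logged construction; treat its
  output as a bound under the stated one-event assumption only.
* WHAM assumes uncorrelated window samples; apply block averaging or
  subsampling before feeding correlated MD series.
* The pipeline driver covers the synthetic end-to-end demonstration;
  real-data workflows are expected to call the library functions
  directly.
* Stationary distributions of reducible rate matrices are ambiguous
  (returned as a flagged per-class mixture).
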