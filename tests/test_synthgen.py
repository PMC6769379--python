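"""Generator-level checks: every synthetic source matches its target law."""

import numpy as np
import pytest

import kgate
from kgate.constants import kt


class TestBindingTrajectories:
    def test_absorbing_apo_spec_stays_unbound(self):
        with pytest.warns(UserWarning, match="degenerate"):
            spec = kgate.RateSpec(states=["apo", "K1"],
                                  rates={("apo", "K1"): 0.0,
                                         ("K1", "apo"): 0.0})
        traces = kgate.gen_binding_traj(spec, duration=10.0, dt=0.01, seed=0)
        tr = traces[0]
        assert np.all(tr.hidden_states == 0)
        assert np.all(tr.trajectory.distances["K1"] > spec.threshold)

    def test_symmetric_two_state_occupies_half(self):
        spec = kgate.RateSpec(states=["apo", "K1"],
                              rates={("apo", "K1"): 1.0, ("K1", "apo"): 1.0})
        traces = kgate.gen_binding_traj(spec, duration=1000.0, dt=0.01, seed=1)
        frac = np.mean(traces[0].hidden_states == 1)
        # ~500 on/off cycles; 3 SE with SE ~ 0.5/sqrt(cycles)
        assert abs(frac - 0.5) < 0.07

    def test_grid_readout_matches_event_driven_dwell(self):
        """State-occupation fractions from the dt grid agree with the exact
        jump-chain dwell times (the discretization loses only sub-frame
        excursions)."""
        spec = kgate.RateSpec(states=["apo", "K1"],
                              rates={("apo", "K1"): 0.5, ("K1", "apo"): 0.8})
        tr = kgate.gen_binding_traj(spec, duration=2000.0, dt=0.01, seed=2)[0]
        grid_frac = np.mean(tr.hidden_states == 1)
        jt = np.append(tr.jump_times, 2000.0)
        dwell = np.diff(jt)
        exact_frac = dwell[tr.jump_states == 1].sum() / 2000.0
        assert abs(grid_frac - exact_frac) < 0.01

    def test_emission_separates_bound_and_unbound(self, two_state_traces):
        spec, traces = two_state_traces
        d = traces[0].trajectory.distances["K1"]
        bound = traces[0].hidden_states == 1
        assert d[bound].max() <= spec.threshold
        assert d[~bound].min() > spec.threshold

    def test_reproducible_given_seed(self):
        spec = kgate.RateSpec.two_state(kd_mm=30.0)
        a = kgate.gen_binding_traj(spec, duration=20.0, dt=0.01, seed=42)
        b = kgate.gen_binding_traj(spec, duration=20.0, dt=0.01, seed=42)
        np.testing.assert_array_equal(a[0].trajectory.distances["K1"],
                                      b[0].trajectory.distances["K1"])
        np.testing.assert_array_equal(a[0].hidden_states, b[0].hidden_states)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kgate.RateSpec(states=[])
        with pytest.raises(ValueError, match="self-transition"):
            kgate.RateSpec(states=["apo"], rates={("apo", "apo"): 1.0})
        with pytest.raises(ValueError, match="negative"):
            kgate.RateSpec(states=["apo", "K1"], rates={("apo", "K1"): -1.0})


class TestLangevin:
    def test_harmonic_variance_matches_equipartition(self):
        a = 100.0  # kJ/mol/nm^2 -> G = a/2 x^2, var = kT/a
        pmf = kgate.AnalyticPMF([0.0, 0.0, a / 2], (-1.0, 1.0))
        x = kgate.gen_langevin_trace(pmf, diffusion=0.1, dt=0.005,
                                     n_steps=400_000, seed=3)
        assert np.var(x[2000:]) == pytest.approx(kt(310.0) / a, rel=0.05)

    def test_flat_profile_is_uniform(self):
        pmf = kgate.AnalyticPMF([0.0], (0.0, 1.0))
        x = kgate.gen_langevin_trace(pmf, diffusion=0.1, dt=0.01,
                                     n_steps=100_000, seed=4)
        assert abs(x.mean() - 0.5) < 0.05
        assert np.var(x) == pytest.approx(1.0 / 12.0, rel=0.15)

    def test_double_well_basin_fraction_matches_quadrature(self):
        pmf = kgate.double_well(barrier=5.0, well=0.5, tilt=2.0,
                                domain=(-1.0, 1.0))
        boundary = pmf.density_minimum()
        x = kgate.gen_langevin_trace(pmf, diffusion=0.1, dt=0.005,
                                     n_steps=400_000, seed=5)
        frac = np.mean(x[5000:] < boundary)
        assert frac == pytest.approx(pmf.basin_fraction(boundary), abs=0.06)


class TestWorkSampler:
    def test_gaussian_crooks_means(self):
        # forward mean dg + s^2/2kT, reverse mean dg - s^2/2kT
        ws = kgate.gen_work_samples(10.0, 2.0, 100_000, 100_000,
                                    temperature=310.0, seed=6)
        shift = 4.0 / (2 * kt(310.0))
        se = 3 * 2.0 / np.sqrt(100_000)
        assert abs(ws.forward.mean() - (10.0 + shift)) < se
        assert abs(ws.reverse.mean() - (10.0 - shift)) < se

    def test_fluctuation_relation_slope_and_intercept(self):
        """ln[P_f(W)/P_r(-W)] is linear in W with slope beta and intercept
        -beta dG."""
        dg, sigma = 7.0, 3.0
        ws = kgate.gen_work_samples(dg, sigma, 100_000, 100_000, seed=7)
        beta = ws.beta
        lo, hi = np.percentile(np.concatenate([ws.forward, ws.reverse]),
                               [10, 90])
        edges = np.linspace(lo, hi, 25)
        hf, _ = np.histogram(ws.forward, bins=edges, density=True)
        hr, _ = np.histogram(ws.reverse, bins=edges, density=True)
        ok = (hf > 0) & (hr > 0)
        w = 0.5 * (edges[:-1] + edges[1:])[ok]
        slope, intercept = np.polyfit(w, np.log(hf[ok] / hr[ok]), 1)
        assert slope == pytest.approx(beta, rel=0.05)
        assert -intercept / slope == pytest.approx(dg, rel=0.05)

    def test_zero_spread_limit(self):
        ws = kgate.gen_work_samples(0.0, 1e-12, 10, 10, seed=8)
        assert np.allclose(ws.forward, 0.0, atol=1e-10)

    def test_bad_temperature_rejected(self):
        with pytest.raises(ValueError):
            kgate.gen_work_samples(1.0, 1.0, 10, 10, temperature=-5.0)


class TestUmbrellaGenerator:
    def test_flat_profile_single_window_is_harmonic(self):
        pmf = kgate.AnalyticPMF([0.0], (-1.0, 1.0))
        uset = kgate.gen_umbrella_set(pmf, [0.2], 1000.0, 50_000, seed=9)
        s = uset.windows[0].samples
        sd_expected = np.sqrt(kt(310.0) / 1000.0)
        assert s.mean() == pytest.approx(0.2, abs=3 * sd_expected / np.sqrt(len(s)))
        assert s.std() == pytest.approx(sd_expected, rel=0.05)

    def test_single_sample_window_flagged(self):
        pmf = kgate.AnalyticPMF([0.0], (-1.0, 1.0))
        with pytest.warns(UserWarning, match="low-sample"):
            kgate.gen_umbrella_set(pmf, [0.0], 1000.0, 1, seed=10)

    def test_poor_overlap_warned(self):
        pmf = kgate.AnalyticPMF([0.0], (-2.0, 2.0))
        with pytest.warns(UserWarning, match="overlap"):
            kgate.gen_umbrella_set(pmf, [-1.5, 1.5], 5000.0, 100, seed=11)

    def test_calibrated_double_well_hits_target_mass(self):
        for target in (0.071, 0.59):
            pmf = kgate.calibrate_double_well(target)
            assert pmf.basin_fraction(pmf.density_minimum()) == \
                pytest.approx(target, abs=1e-4)


class TestCapacitorAndMST:
    def test_null_point_voltage(self):
        series = kgate.gen_capacitor_series(q_p0=2.0, c0=0.5,
                                            q_sol_values=[-2.0, 0.0],
                                            noise_sd=0.0, n_replicates=1,
                                            seed=12)
        v_at_null = series.voltage[series.q_sol == -2.0]
        assert np.allclose(v_at_null, 0.0)

    def test_replicate_voltage_spread_matches_noise(self):
        series = kgate.gen_capacitor_series(q_p0=2.0, c0=0.05,
                                            q_sol_values=[-8.0, -6.0],
                                            noise_sd=5.0, n_replicates=2000,
                                            seed=13)
        sd = series.voltage[series.q_sol == -8.0].std()
        assert sd == pytest.approx(5.0, rel=0.1)

    def test_mst_half_saturation_point(self):
        conc = np.array([0.1, 10.0, 1e6])
        cs = kgate.gen_mst_curves(kd=10.0, amplitude=-0.3, baseline=1.0,
                                  concentrations=conc, noise_sd=0.0,
                                  n_curves=1, seed=14)
        raw = 1.0 - 0.3 * conc / (conc + 10.0)
        np.testing.assert_allclose(cs.curves[0], raw / raw[0], rtol=1e-12)
        # at c = kd the un-normalized signal sits at baseline + amplitude/2
        assert raw[1] == pytest.approx(1.0 - 0.15)

    def test_mst_saturation_limit(self):
        cs = kgate.gen_mst_curves(kd=1.0, amplitude=0.5, baseline=1.0,
                                  concentrations=[1e-3, 1e9], noise_sd=0.0,
                                  n_curves=1, seed=15)
        sat = cs.curves[0, -1] * (1.0 + 0.5 * 1e-3 / (1e-3 + 1.0))
        assert sat == pytest.approx(1.5, rel=1e-3)
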