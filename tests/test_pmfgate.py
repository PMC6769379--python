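"""WHAM profiles, gate boundaries, closed probabilities and efficacy."""

import numpy as np
import pytest

import kgate
from kgate.constants import kt
from kgate.pmfgate import PMFProfile, UmbrellaSet, UmbrellaWindow
from conftest import make_occupancy


def uniform_profile(n=100, lo=0.0, hi=1.0):
    x = np.linspace(lo, hi, n + 1)
    centers = 0.5 * (x[:-1] + x[1:])
    p = np.full(n, 1.0 / (hi - lo))
    return PMFProfile(centers, np.zeros(n), p, None, 310.0, True, 1)


class TestWham:
    def test_unbiased_single_window_is_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.0, 0.3, size=50_000)
        uset = UmbrellaSet([UmbrellaWindow(0.0, 0.0, samples)])
        prof = kgate.wham_profile(uset, n_bins=50, n_boot=0)
        hist, edges = np.histogram(samples, bins=50, density=True)
        with np.errstate(divide="ignore"):
            g_ref = -kt(310.0) * np.log(hist)
        g_ref -= g_ref[np.isfinite(g_ref)].min()
        np.testing.assert_allclose(prof.g, g_ref, atol=1e-9)

    def test_recovers_harmonic_profile(self):
        a = 100.0
        pmf = kgate.AnalyticPMF([0.0, 0.0, a / 2], (-0.8, 0.8))
        centers = np.linspace(-0.7, 0.7, 20)
        uset = kgate.gen_umbrella_set(pmf, centers, 1000.0, 3000, seed=1)
        prof = kgate.wham_profile(uset, n_boot=0)
        allx = np.concatenate(uset.production_samples())
        lo, hi = np.percentile(allx, [5, 95])
        sel = (prof.x >= lo) & (prof.x <= hi)
        g_true = a / 2 * prof.x[sel] ** 2
        resid = prof.g[sel] - g_true
        resid -= resid.mean()            # profiles match up to a constant
        assert np.sqrt(np.mean(resid ** 2)) < 0.2

    def test_double_well_basin_mass_matches_quadrature(self):
        pmf = kgate.calibrate_double_well(0.3)
        centers = np.linspace(*pmf.domain, 44)
        uset = kgate.gen_umbrella_set(pmf, centers, 1000.0, 2000, seed=2)
        prof = kgate.wham_profile(uset, n_boot=40, seed=3)
        boundary = pmf.density_minimum()
        stats = kgate.closed_probability(prof, boundary)
        assert abs(stats.p_closed - 0.3) < 3 * stats.sd + 0.01

    def test_window_order_irrelevant(self):
        pmf = kgate.AnalyticPMF([0.0, 1.0, 10.0], (-0.5, 0.5))
        centers = np.linspace(-0.4, 0.4, 8)
        uset = kgate.gen_umbrella_set(pmf, centers, 800.0, 1000, seed=4)
        shuffled = UmbrellaSet(uset.windows[::-1], uset.temperature)
        a = kgate.wham_profile(uset, n_boot=0, grid_range=(-0.5, 0.5))
        b = kgate.wham_profile(shuffled, n_boot=0, grid_range=(-0.5, 0.5))
        np.testing.assert_allclose(a.g, b.g, atol=1e-6)

    def test_disjoint_windows_rejected(self):
        w1 = UmbrellaWindow(-1.0, 1000.0, np.random.default_rng(5).normal(-1, 0.02, 500))
        w2 = UmbrellaWindow(1.0, 1000.0, np.random.default_rng(6).normal(1, 0.02, 500))
        with pytest.raises(ValueError, match="overlap"):
            kgate.wham_profile(UmbrellaSet([w1, w2]), n_boot=0)


class TestConvergenceAndBoundary:
    def test_identical_blocks_fully_overlap(self):
        prof = uniform_profile()
        ov, passed, _ = kgate.profile_convergence([prof, prof, prof])
        assert ov == pytest.approx(1.0) and passed

    def test_disjoint_blocks_fail(self):
        a = uniform_profile()
        b = uniform_profile()
        p = np.zeros_like(a.p)
        p[:50] = 2.0
        a.p = p
        q = np.zeros_like(b.p)
        q[50:] = 2.0
        b.p = q
        ov, passed, _ = kgate.profile_convergence([a, b, a])
        assert ov == pytest.approx(0.0) and not passed

    def test_stationary_blocks_pass(self):
        pmf = kgate.calibrate_double_well(0.4)
        profs = []
        for k in range(3):
            uset = kgate.gen_umbrella_set(pmf, np.linspace(*pmf.domain, 30),
                                          1000.0, 1500, seed=10 + k)
            profs.append(kgate.wham_profile(uset, n_boot=0,
                                            grid_range=pmf.domain))
        ov, passed, _ = kgate.profile_convergence(profs)
        assert passed

    def test_first_interior_minimum(self):
        counts = [5, 2, 1, 4, 1, 6]
        centers = np.arange(6, dtype=float)
        b = kgate.find_gate_boundary(counts, centers, smoothing_width=0)
        assert b == 2.0

    def test_monotone_histogram_raises(self):
        with pytest.raises(ValueError, match="local minimum"):
            kgate.find_gate_boundary([1, 2, 3, 4, 5], np.arange(5.0),
                                     smoothing_width=0)

    def test_boundary_near_analytic_minimum(self):
        pmf = kgate.calibrate_double_well(0.45)
        grid = np.linspace(*pmf.domain, 200)
        dens = pmf.boltzmann_density(grid)
        b = kgate.find_gate_boundary(dens, grid)
        assert abs(b - pmf.density_minimum()) < 2 * (grid[1] - grid[0])


class TestClosedProbability:
    def test_uniform_density_integral(self):
        stats = kgate.closed_probability(uniform_profile(), 0.3)
        assert stats.p_closed == pytest.approx(0.3, abs=1e-9)
        assert stats.k_close == pytest.approx(3 / 7)

    def test_trace_mode_all_below(self):
        stats = kgate.closed_probability(np.full(100, 1.0), 2.0)
        assert stats.p_closed == 1.0

    def test_trace_mode_monomer_bootstrap(self):
        rng = np.random.default_rng(20)
        monomers = [rng.normal(loc, 0.5, size=400)
                    for loc in (1.0, 1.2, 0.9, 1.1)]
        stats = kgate.closed_probability(monomers, 1.0, seed=21)
        assert 0 < stats.p_closed < 1 and stats.sd > 0

    def test_boundary_outside_support_rejected(self):
        with pytest.raises(ValueError):
            kgate.closed_probability(uniform_profile(), 5.0)


class TestConditionalHistograms:
    def test_partition_identity(self):
        rng = np.random.default_rng(22)
        n = 4000
        states = (rng.random(n) < 0.4).astype(np.int64)
        gate = np.where(states == 1, rng.normal(4, 0.5, n),
                        rng.normal(8, 1.0, n))
        occ = make_occupancy(states)
        traj = kgate.DistanceTrajectory("m", 0.1, {"K1": np.full(n, 5.0)},
                                        gate=gate)
        hists = kgate.conditional_gate_histograms(traj, occ, bins=30)
        assert set(hists) == {"apo", "K1"}
        edges = hists["apo"][1]
        total, _ = np.histogram(gate, bins=edges, density=True)
        combined = sum(dens * nf for dens, _, nf in hists.values()) / n
        np.testing.assert_allclose(combined, total, atol=1e-12)

    def test_distinct_emission_regimes_separate(self):
        rng = np.random.default_rng(23)
        n = 6000
        states = np.repeat([0, 1], n // 2)
        gate = np.where(states == 1, rng.normal(4, 0.3, n),
                        rng.normal(9, 0.3, n))
        occ = make_occupancy(states)
        traj = kgate.DistanceTrajectory("m", 0.1, {"K1": np.full(n, 5.0)},
                                        gate=gate)
        hists = kgate.conditional_gate_histograms(traj, occ, bins=40)
        mean = {k: np.average(0.5 * (e[:-1] + e[1:]), weights=d + 1e-300)
                for k, (d, e, _) in hists.items()}
        assert mean["K1"] == pytest.approx(4.0, abs=0.1)
        assert mean["apo"] == pytest.approx(9.0, abs=0.1)


class TestAllostericEfficacy:
    def test_odds_ratio_identities(self):
        assert kgate.allosteric_efficacy(0.25, 0.25)[0] == pytest.approx(1.0)
        assert kgate.allosteric_efficacy(1 / 3, 2 / 3)[0] == pytest.approx(4.0)

    def test_degenerate_probability_rejected(self):
        with pytest.raises(ValueError):
            kgate.allosteric_efficacy(0.0, 0.5)
        with pytest.raises(ValueError):
            kgate.allosteric_efficacy(0.5, 1.0)

    def test_recovery_with_paired_bootstrap(self):
        """Efficacy calibrated to an odds ratio of 20 is recovered within
        3 SD from finite closed-fraction estimates."""
        rng = np.random.default_rng(24)
        p_a, n = 0.071, 5000
        odds_a = p_a / (1 - p_a)
        p_b = 20 * odds_a / (1 + 20 * odds_a)
        boot_a = rng.binomial(n, p_a, size=2000) / n
        boot_b = rng.binomial(n, p_b, size=2000) / n
        alpha, sd = kgate.allosteric_efficacy(p_a, p_b, boot_a, boot_b,
                                              seed=25)
        assert abs(alpha - 20.0) < 3 * sd


class TestRmsfAndHist2d:
    def test_static_coordinates_zero(self):
        coords = np.ones((100, 5, 3))
        mean, sd = kgate.rmsf_blocks(coords, n_blocks=10)
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(sd, 0.0)

    def test_isotropic_jitter_gives_s_sqrt3(self):
        rng = np.random.default_rng(26)
        s = 0.4
        coords = rng.normal(0.0, s, size=(20_000, 3, 3))
        mean, sd = kgate.rmsf_blocks(coords, n_blocks=10)
        np.testing.assert_allclose(mean, s * np.sqrt(3), rtol=0.03)

    def test_duplicated_trajectory_same_mean(self):
        rng = np.random.default_rng(27)
        coords = rng.normal(size=(200, 4, 3))
        m1, _ = kgate.rmsf_blocks(coords, n_blocks=10)
        m2, _ = kgate.rmsf_blocks(np.concatenate([coords, coords]),
                                  n_blocks=20)
        np.testing.assert_allclose(m1, m2, rtol=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            kgate.rmsf_blocks(np.ones((5, 2, 3)), n_blocks=10)

    def test_quadrants_sum_to_one(self):
        rng = np.random.default_rng(28)
        gate = rng.uniform(0, 10, 5000)
        pair = rng.uniform(0, 10, 5000)
        _, _, _, quad = kgate.hist2d_gate_saltbridge(gate, pair, (5.0, 5.0))
        assert sum(quad.values()) == pytest.approx(1.0)

    def test_correlated_series_fill_diagonal_quadrants(self):
        x = np.linspace(0, 10, 1000)
        _, _, _, quad = kgate.hist2d_gate_saltbridge(x, x, (5.0, 5.0))
        assert quad["closed/broken"] == 0.0
        assert quad["open/formed"] == 0.0

    def test_independent_series_factorize(self):
        rng = np.random.default_rng(29)
        gate = rng.uniform(0, 10, 200_000)
        pair = rng.uniform(0, 10, 200_000)
        _, _, _, quad = kgate.hist2d_gate_saltbridge(gate, pair, (3.0, 7.0))
        assert quad["closed/formed"] == pytest.approx(0.3 * 0.7, abs=0.01)
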