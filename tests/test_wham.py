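import numpy as np
import pytest

import pmfkit as pk
from pmfkit.geometry import TimeSeries
from pmfkit.wham import UmbrellaWindow, build_histograms, solve_wham

from _oracles import naive_wham

KT310 = pk.kt(310.0)


def window_from_values(values, center=0.5, k=1000.0, wid="w0"):
    times = np.arange(len(values), dtype=float)
    return UmbrellaWindow(wid, center, k, TimeSeries(times, values))


class TestHarmonicBias:
    @pytest.mark.parametrize(
        "xi, center, expected",
        [
            (0.5, 0.5, 0.0),
            (0.55, 0.5, 1.25),
            (0.4, 0.5, 5.0),
            (0.6, 0.5, 5.0),
        ],
    )
    def test_values(self, xi, center, expected):
        win = window_from_values([center], center=center, k=1000.0)
        assert pk.harmonic_bias(xi, win) == pytest.approx(expected)

    def test_vectorized(self):
        win = window_from_values([0.5], center=0.5, k=1000.0)
        np.testing.assert_allclose(
            pk.harmonic_bias(np.array([0.4, 0.5, 0.6]), win), [5.0, 0.0, 5.0]
        )


class TestBuildHistograms:
    def test_single_bin_counts(self):
        win = window_from_values([0.501, 0.502, 0.503, 0.504])
        hist = build_histograms([win], bin_width=0.01, burn_in_fraction=0.0)
        assert hist.counts.sum() == 4
        assert hist.counts.max() == 4

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        wins = [
            window_from_values(rng.uniform(0.4, 0.8, size=50), wid=f"w{i}")
            for i in range(4)
        ]
        hist = build_histograms(wins, bin_width=0.01, burn_in_fraction=0.1)
        np.testing.assert_array_equal(hist.n_i, [45, 45, 45, 45])
        assert hist.counts.sum() == 180

    def test_sample_on_interior_edge_goes_to_upper_bin(self):
        win = window_from_values([0.49, 0.5, 0.51])
        hist = build_histograms([win], bin_width=0.01, burn_in_fraction=0.0)
        edge_bin = int(np.searchsorted(hist.grid.edges, 0.5))
        # the 0.5 sample shares the bin whose lower edge is 0.5
        assert hist.grid.edges[edge_bin] == pytest.approx(0.5)
        assert hist.counts[0, edge_bin] == 1

    def test_burn_in_never_empties_a_window(self):
        # a single-sample window survives any valid burn-in fraction
        win = window_from_values([0.5], wid="w7")
        hist = build_histograms([win], bin_width=0.01, burn_in_fraction=0.9)
        assert hist.n_i[0] == 1


class TestSolveWham:
    def test_boltzmann_inversion_limit_bitwise(self):
        """One unbiased window: WHAM must return exactly the normalized
        raw histogram."""
        s = pk.make_dimer_surface(kind="linear")
        ts = pk.sample_window(s, center=1.0, k=0.0, n=20000, seed=1)
        win = UmbrellaWindow("w0", 1.0, 0.0, ts)
        hist = build_histograms([win], bin_width=0.02, burn_in_fraction=0.0)
        sol = solve_wham(hist, [win], temperature=310.0)
        raw = hist.counts[0]
        expected = raw / raw.sum()
        np.testing.assert_array_equal(sol.p, expected)
        assert sol.f_i[0] == 0.0

    def test_symmetric_windows_equal_shifts(self):
        """Two windows mirror-placed on a symmetric surface get equal F_i."""
        rng = np.random.default_rng(3)
        sigma = np.sqrt(KT310 / 1000.0)
        left = rng.normal(0.9, sigma, 4000)
        right = 2.0 - left  # exact mirror about 1.0
        wins = [
            window_from_values(left, center=0.9, wid="wl"),
            window_from_values(right, center=1.1, wid="wr"),
        ]
        hist = build_histograms(wins, bin_width=0.01, burn_in_fraction=0.0)
        sol = solve_wham(hist, wins, temperature=310.0, tol=1e-8)
        assert sol.converged
        assert abs(sol.f_i[1] - sol.f_i[0]) < 1e-2

    def test_oracle_equivalence_small_experiments(self, dimer_surface_linear):
        """Production solver matches a brute-force naive fixed point
        within 0.01 kT on random small experiments."""
        for seed in (101, 202, 303):
            cfg = pk.GeneratorConfig(
                n_windows=6, spacing=0.1, samples_per_window=300,
                seed=seed, xi_start=0.6,
            )
            exp = pk.generate_experiment(dimer_surface_linear, cfg)
            hist = build_histograms(list(exp.windows), bin_width=0.06,
                                    burn_in_fraction=0.1)
            assert hist.grid.n_bins <= 20
            sol = solve_wham(hist, list(exp.windows), temperature=310.0,
                             tol=1e-9)
            _, f_oracle = naive_wham(
                hist.counts.tolist(),
                hist.grid.centers.tolist(),
                [w.center for w in exp.windows],
                [w.k for w in exp.windows],
                310.0,
            )
            np.testing.assert_allclose(sol.f_i, f_oracle, atol=0.01 * KT310)

    def test_fixed_point_residual(self, small_experiment):
        """Plugging the converged P back into the F_i equation reproduces
        F_i within tol."""
        wins = list(small_experiment.windows)
        hist = build_histograms(wins, bin_width=0.02, burn_in_fraction=0.1)
        sol = solve_wham(hist, wins, tol=1e-7)
        assert sol.converged
        beta = 1.0 / KT310
        occ = sol.p > 0
        centers = hist.grid.centers[occ]
        f_check = np.array([
            -KT310 * np.log(np.sum(
                sol.p[occ] * np.exp(-beta * pk.harmonic_bias(centers, w))
            ))
            for w in wins
        ])
        f_check -= f_check[0]
        np.testing.assert_allclose(sol.f_i, f_check, atol=1e-6)

    def test_disconnected_support_raises(self):
        a = window_from_values(np.full(10, 0.5), center=0.5, wid="a")
        b = window_from_values(np.full(10, 3.0), center=3.0, wid="b")
        hist = build_histograms([a, b], bin_width=0.01, burn_in_fraction=0.0)
        with pytest.raises(ValueError, match="disconnected"):
            solve_wham(hist, [a, b])

    def test_non_convergence_warns_and_flags(self, small_experiment):
        wins = list(small_experiment.windows)
        hist = build_histograms(wins, bin_width=0.02, burn_in_fraction=0.1)
        with pytest.warns(RuntimeWarning, match="converge"):
            sol = solve_wham(hist, wins, tol=1e-12, max_iter=3)
        assert not sol.converged
        assert sol.residual > 0


class TestJacobianCorrection:
    def test_zero_at_one_nm(self):
        assert pk.jacobian_correction(1.0, 310.0) == 0.0
        assert pk.jacobian_correction(1.0, 200.0) == 0.0

    def test_magnitude_at_e_nm(self):
        assert abs(pk.jacobian_correction(np.e, 310.0)) == pytest.approx(
            2 * KT310, abs=1e-9
        )
        assert pk.jacobian_correction(np.e, 310.0) == pytest.approx(5.155, abs=1e-3)

    def test_rejects_non_positive_xi(self):
        with pytest.raises(ValueError):
            pk.jacobian_correction(0.0, 310.0)
        with pytest.raises(ValueError):
            pk.jacobian_correction(np.array([1.0, -2.0]), 310.0)


class TestPmfFromSolution:
    def _uniform_solution(self, p=None, n=50):
        edges = np.linspace(1.0, 2.0, n + 1)
        grid = pk.BinGrid(edges)
        if p is None:
            p = np.full(n, 1.0 / n)
        return pk.WhamSolution(grid, p, np.zeros(1), 310.0, 1, True, 0.0)

    def test_uniform_p_linear_gives_zero(self):
        sol = self._uniform_solution()
        prof = pk.pmf_from_solution(sol, apply_correction=False,
                                    plateau_region=(1.0, 2.0))
        np.testing.assert_allclose(prof.w, 0.0, atol=1e-12)

    def test_xi_squared_p_radial_gives_zero_after_correction(self):
        sol = self._uniform_solution()
        p = sol.grid.centers**2
        p /= p.sum()
        sol = self._uniform_solution(p=p)
        prof = pk.pmf_from_solution(sol, apply_correction=True,
                                    plateau_region=(1.0, 2.0))
        # exact up to the bin-center-vs-bin-average discretization
        np.testing.assert_allclose(prof.w, 0.0, atol=1e-4)

    def test_shift_invariance(self, small_experiment):
        """Adding a constant to W before plateau-zeroing cannot change the
        final profile: doubling all counts leaves the PMF identical."""
        wins = list(small_experiment.windows)
        opts = pk.AnalysisOptions(plateau_region=None)
        hist = build_histograms(wins, 0.02, 0.1)
        sol = solve_wham(hist, wins, tol=1e-8)
        region = (0.4, 0.6)
        prof1 = pk.pmf_from_solution(sol, plateau_region=region)
        # scaling P by a constant adds -kT ln 2 to every W value; the
        # plateau shift must absorb it exactly
        from dataclasses import replace
        sol2 = replace(sol, p=sol.p * 2.0)
        prof2 = pk.pmf_from_solution(sol2, plateau_region=region)
        np.testing.assert_allclose(prof1.w, prof2.w, equal_nan=True, atol=1e-10)
        assert prof2.shift_c == pytest.approx(prof1.shift_c - KT310 * np.log(2))

    def test_empty_bins_masked_and_plateau_must_be_occupied(self):
        edges = np.linspace(0.0, 1.0, 11)
        p = np.array([0.2, 0.2, 0.0, 0.2, 0.2, 0.2, 0.0, 0.0, 0.0, 0.0])
        sol = pk.WhamSolution(pk.BinGrid(edges), p, np.zeros(1), 310.0, 1, True, 0.0)
        prof = pk.pmf_from_solution(sol, plateau_region=(0.0, 0.2))
        assert np.isnan(prof.w[2])
        with pytest.raises(ValueError, match="empty"):
            pk.pmf_from_solution(sol, plateau_region=(0.55, 0.95))


def test_double_well_recovery_rmsd(dimer_surface_linear):
    """30 windows over the double well: recovered -kT ln P matches the
    generating surface to < 0.5 kJ/mol RMSD near the minimum."""
    cfg = pk.GeneratorConfig(n_windows=30, spacing=0.05,
                             samples_per_window=2000, seed=8, xi_start=0.3)
    exp = pk.generate_experiment(dimer_surface_linear, cfg)
    _, sol, prof = pk.analyze_windows(
        list(exp.windows), pk.AnalysisOptions(plateau_region=None)
    )
    occ = prof.occupied
    true = dimer_surface_linear.w(prof.xi[occ])
    near = true <= true.min() + 10.0
    diff = prof.w[occ][near] - true[near]
    diff -= diff.mean()
    assert np.sqrt(np.mean(diff**2)) < 0.5


def test_monotone_region_recovered_monotone(dimer_surface_linear):
    """Where the generating surface rises monotonically and windows cover it
    well, the recovered profile is monotone up to small noise."""
    cfg = pk.GeneratorConfig(n_windows=12, spacing=0.05,
                             samples_per_window=3000, seed=12, xi_start=0.5)
    exp = pk.generate_experiment(dimer_surface_linear, cfg)
    _, sol, prof = pk.analyze_windows(
        list(exp.windows),
        pk.AnalysisOptions(bin_width=0.02, plateau_region=None),
    )
    occ = prof.occupied & (prof.xi > 0.55) & (prof.xi < 0.8)
    w = prof.w[occ]
    # steep monotone rise from the contact well: allow small noise backsteps
    assert np.all(np.diff(w) > -0.5)
    assert w[-1] > w[0] + 10
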