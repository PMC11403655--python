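import json

import numpy as np
import pytest
from scipy.stats import kstest

import pmfkit as pk


class TestDimerSurface:
    def test_constructed_depths_and_plateau(self):
        s = pk.make_dimer_surface(
            depth_contact=-32.0, xi_contact=0.5,
            depth_solventsep=-4.0, xi_solventsep=1.2, plateau_onset=2.5,
        )
        assert s.w(0.5) == pytest.approx(-32.0)
        assert s.w(1.2) == pytest.approx(-4.0)
        assert s.w(4.0) == 0.0
        assert s.w(2.5) == 0.0

    def test_zero_depths_give_flat_surface(self):
        s = pk.make_dimer_surface(depth_contact=0.0, depth_solventsep=0.0,
                                  barrier=0.0)
        grid = np.linspace(0.3, 4.3, 500)
        np.testing.assert_allclose(s.w(grid), 0.0, atol=1e-12)

    def test_exactly_two_local_minima_for_defaults(self):
        s = pk.make_dimer_surface()
        grid = np.linspace(*s.support, 4001)
        w = s.w(grid)
        strict_min = (w[1:-1] < w[:-2]) & (w[1:-1] < w[2:])
        assert strict_min.sum() == 2
        xi_minima = grid[1:-1][strict_min]
        assert xi_minima[0] == pytest.approx(0.5, abs=0.01)
        assert xi_minima[1] == pytest.approx(1.2, abs=0.01)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="xi_contact"):
            pk.make_dimer_surface(xi_contact=1.5, xi_solventsep=1.2)
        with pytest.raises(ValueError, match="depth"):
            pk.make_dimer_surface(depth_contact=5.0)


class TestSampleWindow:
    def test_harmonic_bias_std_on_flat_surface(self):
        """On a flat surface a K=1000 window samples a Gaussian of width
        sqrt(kT/K) ~ 0.0508 nm at 310 K."""
        s = pk.flat_surface("linear")
        ts = pk.sample_window(s, center=2.0, k=1000.0, temperature=310.0,
                              n=20000, seed=2)
        target = np.sqrt(pk.kt(310.0) / 1000.0)
        assert ts.values.std(ddof=1) == pytest.approx(target, rel=0.05)

    def test_same_seed_identical_series(self):
        s = pk.flat_surface("linear")
        a = pk.sample_window(s, 1.0, 1000.0, n=500, seed=9)
        b = pk.sample_window(s, 1.0, 1000.0, n=500, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        c = pk.sample_window(s, 1.0, 1000.0, n=500, seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_center_outside_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            pk.sample_window(pk.flat_surface("linear"), center=99.0, k=1000.0)

    def test_stationarity_ks_on_biased_window(self):
        """Empirical CDF matches the numerically integrated target CDF."""
        s = pk.make_dimer_surface(kind="linear")
        center, k, temp = 0.6, 1000.0, 310.0
        ts = pk.sample_window(s, center, k, temp, n=30000, seed=3)
        grid = np.linspace(*s.support, 20001)
        logw = -(s.w(grid) + 0.5 * k * (grid - center) ** 2) / pk.kt(temp)
        dens = np.exp(logw - logw.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        stat = kstest(ts.values, lambda q: np.interp(q, grid, cdf)).statistic
        assert stat < 0.02

    def test_radial_convention_tracks_xi_squared(self):
        """Free radial sampling has density proportional to xi^2."""
        lo, hi = 0.5, 3.5
        s = pk.flat_surface("radial", support=(lo, hi))
        ts = pk.sample_window(s, center=2.0, k=0.0, n=30000, seed=4)
        # analytic CDF of p(x) ~ x^2 on [lo, hi]
        stat = kstest(
            ts.values, lambda q: (q**3 - lo**3) / (hi**3 - lo**3)
        ).statistic
        assert stat < 0.02


class TestGenerateExperiment:
    def test_default_layout_written(self, tmp_path, dimer_surface_radial):
        cfg = pk.GeneratorConfig(samples_per_window=20, seed=1)
        exp = pk.generate_experiment(dimer_surface_radial, cfg, out_dir=tmp_path)
        assert len(exp.windows) == 80
        assert len(list((tmp_path / "windows").glob("*.xvg"))) == 80
        records = pk.read_window_metadata(tmp_path / "metadata.tsv")
        assert len(records) == 80
        centers = np.array([r.center_nm for r in records])
        np.testing.assert_allclose(np.diff(centers), 0.05)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["seed"] == 1
        assert manifest["surface"]["kind"] == "radial"

    def test_single_window_accepted(self, dimer_surface_linear):
        cfg = pk.GeneratorConfig(n_windows=1, samples_per_window=50, seed=0,
                                 xi_start=0.5)
        exp = pk.generate_experiment(dimer_surface_linear, cfg)
        assert len(exp.windows) == 1

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            pk.GeneratorConfig(samples_per_window=0)

    def test_centers_beyond_support_rejected(self, dimer_surface_linear):
        cfg = pk.GeneratorConfig(n_windows=100, spacing=0.05, xi_start=0.5,
                                 samples_per_window=10)
        with pytest.raises(ValueError, match="support"):
            pk.generate_experiment(dimer_surface_linear, cfg)


class TestDistanceTraces:
    def test_planted_labels_match_tail_behaviour(self):
        spec = pk.AbandonmentSpec.with_n_abandoned(80, 16)
        traces = pk.make_distance_traces(spec, n_samples=400, seed=5)
        assert len(traces) == 80
        midpoint = 0.5 * (spec.bound_level + spec.unbound_level)
        tail_high = [
            float(np.mean(t.series.tail(0.2).values)) > midpoint for t in traces
        ]
        assert sum(tail_high) == 16
        assert tail_high == list(spec.labels)

    def test_zero_labeled_stay_bound(self):
        spec = pk.AbandonmentSpec.with_n_abandoned(10, 0)
        traces = pk.make_distance_traces(spec, n_samples=300, seed=6)
        for t in traces:
            assert abs(float(np.mean(t.series.values)) - spec.bound_level) < 0.05

    def test_same_seed_identical_traces(self):
        spec = pk.AbandonmentSpec.with_n_abandoned(5, 2)
        a = pk.make_distance_traces(spec, n_samples=100, seed=7)
        b = pk.make_distance_traces(spec, n_samples=100, seed=7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.series.values, tb.series.values)

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            pk.AbandonmentSpec(labels=(True,), bound_level=1.0, unbound_level=0.5)
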