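import numpy as np
import pytest

import finebin as fb
from finebin import FineGrid
from finebin.kde import _Quadrature, _component_densities


def _density_integral(est):
    return est.density.sum()  # unit bins: sum of masses


class TestIceKde:
    def test_one_iteration_matches_smeared_uniform_oracle(self):
        """First iterate = kernel-smeared within-bin-uniform mixture, computed
        independently from the closed-form Gaussian-uniform convolution."""
        gc = fb.GroupedCounts([0, 5, 10, 15], [5, 10, 5])
        grid = FineGrid(0, 15)
        est = fb.ice_kde(gc, 2.0, grid, max_iter=1, tol=0)
        q = _Quadrature(grid, gc.edges)
        oracle = _component_densities(q, gc.edges, 2.0) @ (gc.counts / gc.total_n)
        oracle /= q.w @ oracle
        gamma_oracle = gc.total_n * (q.unit_w.T @ oracle)
        assert np.max(np.abs(est.gamma - gamma_oracle)) / gc.total_n < 2e-3

    def test_symmetric_input_gives_symmetric_output(self):
        gc = fb.GroupedCounts([0, 5, 10, 15, 20], [3, 8, 8, 3])
        est = fb.ice_kde(gc, 2.0, FineGrid(0, 20))
        np.testing.assert_allclose(est.gamma, est.gamma[::-1], atol=1e-10)

    def test_small_bandwidth_approaches_histogram(self):
        """As h -> 0 the kernel tends to a delta and the iteration leaves the
        histogram density (nearly) fixed."""
        gc = fb.GroupedCounts([0, 10], [40])
        # a delta-like kernel makes each smearing step nearly the identity;
        # a few steps leave the histogram essentially unchanged
        est = fb.ice_kde(gc, 0.05, FineGrid(0, 10), max_iter=5)
        np.testing.assert_allclose(est.density[1:-1], 0.1, atol=2e-3)

    def test_unit_bins_first_iterate_close_to_midpoint_kde(self):
        """With width-1 grouping the smeared-uniform start is within O(w^2)
        of the classical midpoint KDE."""
        counts = np.r_[np.zeros(3), [1, 3, 7, 9, 7, 3, 1], np.zeros(5)]
        gc = fb.GroupedCounts(np.arange(0, 16.0), counts)
        grid = FineGrid(0, 15)
        est = fb.ice_kde(gc, 3.0, grid, max_iter=1, tol=0)
        q = _Quadrature(grid, gc.edges)
        mids = (gc.edges[:-1] + gc.edges[1:]) / 2.0
        kde = sum(
            c * np.exp(-0.5 * ((q.nodes - m) / 3.0) ** 2)
            for m, c in zip(mids, gc.counts)
        ) / (3.0 * np.sqrt(2 * np.pi))
        kde /= q.w @ kde
        gamma_mid = gc.total_n * (q.unit_w.T @ kde)
        assert np.max(np.abs(est.gamma - gamma_mid)) / gc.total_n < 1e-4

    def test_density_normalized_and_damped(self, scheme_a_replicate):
        gc, grid = scheme_a_replicate
        est = fb.ice_kde(gc, fb.plugin_bandwidth(gc), grid)
        assert abs(_density_integral(est) - 1.0) < 1e-6
        hist = est.settings["sup_change_history"]
        assert all(a >= b for a, b in zip(hist[-3:], hist[-2:]))  # damped tail

    def test_rejects_bad_inputs(self):
        gc = fb.GroupedCounts([0, 5], [3])
        with pytest.raises(ValueError):
            fb.ice_kde(gc, -1.0)
        with pytest.raises(ValueError):
            fb.ice_kde(fb.GroupedCounts([0, 5], [0]), 1.0)


class TestBootKde:
    def test_seeded_runs_are_bitwise_identical(self):
        gc = fb.GroupedCounts([0, 5, 10], [10, 20])
        a = fb.boot_kde(gc, 2.0, B=1, seed=7)
        b = fb.boot_kde(gc, 2.0, B=1, seed=7)
        np.testing.assert_array_equal(a.gamma, b.gamma)

    def test_one_bin_mean_is_symmetric(self):
        """Monte-Carlo: B=500 replicates of a single uniform bin give a
        density symmetric about the bin midpoint (|skew| < 0.05)."""
        gc = fb.GroupedCounts([5, 10], [50])
        est = fb.boot_kde(gc, 1.0, FineGrid(0, 15), B=500, seed=3)
        xs = est.grid.points + 0.5
        d = est.density
        mean = float(d @ xs)
        var = float(d @ (xs - mean) ** 2)
        skew = float(d @ (xs - mean) ** 3) / var**1.5
        assert abs(mean - 7.5) < 0.05
        assert abs(skew) < 0.05

    def test_density_integrates_to_one(self, scheme_a_replicate):
        gc, grid = scheme_a_replicate
        est = fb.boot_kde(gc, "auto", grid, B=50, seed=0)
        assert abs(_density_integral(est) - 1.0) < 1e-6
        assert est.settings["h"] > 0

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            fb.boot_kde(fb.GroupedCounts([0, 5], [3]), 1.0, B=0)


class TestPluginBandwidth:
    def test_narrow_bin_gives_small_h(self):
        gc = fb.GroupedCounts([0, 1, 2, 50], [0, 40, 0])
        assert fb.plugin_bandwidth(gc) < 1.0

    def test_n_scaling(self, scheme_a_replicate):
        """Doubling every count leaves the pseudo-data shape unchanged, so
        h shrinks by about 2^(-1/5)."""
        gc, _ = scheme_a_replicate
        h1 = fb.plugin_bandwidth(gc)
        h2 = fb.plugin_bandwidth(fb.GroupedCounts(gc.edges, gc.counts * 2))
        assert abs(h2 / h1 - 2 ** (-1 / 5)) < 0.05

    def test_sanity_envelope_on_scenario_replicate(self, scheme_a_replicate):
        gc, _ = scheme_a_replicate
        assert 1.0 <= fb.plugin_bandwidth(gc) <= 10.0


class TestLcvBandwidth:
    def test_single_candidate_returned(self):
        gc = fb.GroupedCounts([0, 5, 10], [10, 20])
        assert fb.lcv_bandwidth(gc, h_grid=[2.5]) == 2.5

    def test_returns_grid_argmax(self, scheme_a_replicate):
        gc, _ = scheme_a_replicate
        from finebin.kde import DEFAULT_H_GRID, _MASS_FLOOR

        h = fb.lcv_bandwidth(gc)
        grid = fb.FineGrid.spanning(gc)
        q = _Quadrature(grid, gc.edges)

        def score(hh):
            comp = _component_densities(q, gc.edges, hh)
            full = comp @ gc.counts
            s = 0.0
            for i in range(gc.nbins):
                c = gc.counts[i]
                if c == 0:
                    continue
                mass = float(q.bin_w[:, i] @ ((full - c * comp[:, i]) / (gc.total_n - c)))
                if mass <= _MASS_FLOOR:
                    return -np.inf
                s += c * np.log(mass)
            return s

        scores = [score(hh) for hh in DEFAULT_H_GRID]
        assert score(h) == max(scores)

    def test_oversmooths_relative_to_plugin(self, scheme_a_replicate):
        """Whole-bin holdout pushes the bandwidth up: cross-validation
        oversmooths compared with the plug-in choice on grouped data."""
        gc, _ = scheme_a_replicate
        assert fb.lcv_bandwidth(gc) >= fb.plugin_bandwidth(gc)
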