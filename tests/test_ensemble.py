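"""Population statistics: histograms, cv, Hill fits, temporal divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from luxtrace.ensemble import (
    DoseResponsePoint,
    autocorrelation_divergence,
    brightness_distribution,
    coefficient_of_variation,
    fit_hill,
    normalized_histogram,
    per_cell_level,
)
from luxtrace.synthetic import HillParams, bulk_response
from luxtrace.trajectories import Trajectory, smooth_series


def flat_trajs(levels, n_frames=26, dt=10.0, noise=0.0, seed=0, filter_sd=0.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    out = []
    for i, lv in enumerate(levels):
        raw = lv + (rng.normal(0, noise, t.size) if noise else 0.0)
        raw = np.asarray(raw, float) if np.ndim(raw) else np.full(t.size, raw)
        sm = smooth_series(t, raw, filter_sd) if filter_sd > 0 else raw.copy()
        out.append(Trajectory(i, t, raw, sm, filter_sd))
    return out


class TestBrightnessDistribution:
    def test_identical_levels_single_bin(self):
        trajs = flat_trajs([50.0] * 8)
        d = brightness_distribution(trajs, t=100.0, bin_edges=np.arange(0, 101, 10))
        assert d.counts.sum() == 8
        assert (d.counts > 0).sum() == 1
        assert d.median == d.q25 == d.q75 == 50.0

    def test_quartiles_by_linear_interpolation(self):
        trajs = flat_trajs([10.0, 20.0, 30.0, 40.0])
        d = brightness_distribution(trajs, t=100.0, bin_edges=np.arange(0, 51, 5))
        assert d.median == pytest.approx(25.0)
        assert d.q25 == pytest.approx(17.5)
        assert d.q75 == pytest.approx(32.5)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            brightness_distribution([], 0.0, [0, 1])


class TestCoefficientOfVariation:
    def test_identical_levels_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_example(self):
        # sd = sqrt(20/3), mean = 5
        assert coefficient_of_variation([2, 4, 6, 8]) == pytest.approx(0.5164, abs=2e-4)

    def test_undefined_for_nonpositive_mean(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    @settings(max_examples=25, deadline=None)
    @given(factor=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, factor):
        rng = np.random.default_rng(11)
        x = rng.gamma(2.0, 10.0, 40)
        assert coefficient_of_variation(factor * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9)


class TestHillFit:
    def _points(self, hill, ais, noise=0.0, rng=None, n_cells=10):
        ys = bulk_response(np.asarray(ais, float), hill)
        if noise:
            ys = ys * (1 + rng.normal(0, noise, ys.size))
        return [DoseResponsePoint(ai=a, per_cell_levels=np.full(n_cells, y))
                for a, y in zip(ais, ys)]

    def test_noiseless_round_trip_to_four_significant_figures(self):
        hill = HillParams(k_eq=200.0, hill_n=2.6, i_max=38.0, i_base=2.0)
        pts = self._points(hill, [0, 25, 50, 100, 200, 400, 700, 1000])
        fit = fit_hill(pts)
        assert fit.converged and not fit.flags
        assert fit.params.k_eq == pytest.approx(200.0, rel=5e-5)
        assert fit.params.hill_n == pytest.approx(2.6, rel=5e-5)

    @settings(max_examples=15, deadline=None)
    @given(k=st.floats(min_value=30.0, max_value=600.0),
           n=st.floats(min_value=1.0, max_value=4.0),
           imax=st.floats(min_value=10.0, max_value=300.0))
    def test_oracle_equivalence_on_model_data(self, k, n, imax):
        hill = HillParams(k_eq=k, hill_n=n, i_max=imax, i_base=imax / 20)
        ais = [0, k / 4, k / 2, k, 2 * k, 4 * k, 8 * k]
        fit = fit_hill(self._points(hill, ais))
        assert fit.params.k_eq == pytest.approx(k, rel=1e-3)
        assert fit.params.hill_n == pytest.approx(n, rel=1e-3)

    def test_flat_points_flagged(self):
        pts = [DoseResponsePoint(ai=a, per_cell_levels=np.full(5, 20.0))
               for a in (0, 10, 100, 1000)]
        fit = fit_hill(pts)
        assert "no_half_maximum_bracketing" in fit.flags

    def test_noisy_monte_carlo_recovery(self):
        hill = HillParams(k_eq=200.0, hill_n=2.6, i_max=38.0, i_base=2.0)
        rng = np.random.default_rng(5)
        keqs, ns = [], []
        for _ in range(100):
            pts = self._points(hill, [0, 25, 50, 100, 200, 400, 700, 1000],
                               noise=0.05, rng=rng)
            fit = fit_hill(pts)
            keqs.append(fit.params.k_eq)
            ns.append(fit.params.hill_n)
        assert abs(np.median(keqs) - 200.0) < 0.05 * 200.0
        assert abs(np.median(ns) - 2.6) < 0.15 * 2.6

    def test_needs_four_distinct_levels(self):
        hill = HillParams(k_eq=100.0, hill_n=2.0, i_max=30.0)
        with pytest.raises(ValueError):
            fit_hill(self._points(hill, [0, 100, 1000]))


class TestDivergence:
    def test_constant_trajectories_zero_sigma(self):
        trajs = flat_trajs([10.0, 40.0, 90.0])
        curve = autocorrelation_divergence(trajs, [10, 20, 40], t_min=0)
        assert np.allclose(curve.sigma_d, 0.0)

    def test_additive_offset_invariance_and_scale_equivariance(self):
        trajs = flat_trajs(np.linspace(20, 200, 12), noise=5.0, seed=3)
        base = autocorrelation_divergence(trajs, [10, 30], t_min=0).sigma_d
        shifted = [Trajectory(t.cell_id, t.times, t.raw + 100, t.smoothed + 100,
                              t.filter_sd) for t in trajs]
        scaled = [Trajectory(t.cell_id, t.times, 3 * t.raw, 3 * t.smoothed,
                             t.filter_sd) for t in trajs]
        assert np.allclose(
            autocorrelation_divergence(shifted, [10, 30], t_min=0).sigma_d, base,
            rtol=1e-9)
        assert np.allclose(
            autocorrelation_divergence(scaled, [10, 30], t_min=0).sigma_d, 3 * base,
            rtol=1e-9)

    def test_iid_jitter_matches_monte_carlo_oracle(self):
        # flat trajectories of diverse baselines + iid Gaussian jitter:
        # the pooled-scatter line has slope ~1, so sigma_d ~ s*sqrt(2).
        # The expected value is computed by an independent brute-force
        # simulation of (x, y) pairs rather than the approximation.
        s = 5.0
        baselines = np.linspace(20, 300, 25)
        rng = np.random.default_rng(8)
        x = np.repeat(baselines, 2000) + rng.normal(0, s, 25 * 2000)
        y = np.repeat(baselines, 2000) + rng.normal(0, s, 25 * 2000)
        slope, intercept = np.polyfit(x, y, 1)
        oracle = np.std(y - (intercept + slope * x), ddof=1)

        trajs = flat_trajs(baselines, n_frames=40, noise=s, seed=9)
        curve = autocorrelation_divergence(trajs, [10], t_min=0)
        assert curve.sigma_d[0] == pytest.approx(oracle, rel=0.05)

    def test_smoothing_dip_at_one_kernel_width(self):
        # Gaussian filtering correlates nearby frames: sigma_d at tau = 10
        # (one kernel sd) dips below sigma_d at tau = 40
        trajs = flat_trajs(np.linspace(30, 200, 10), n_frames=30, noise=8.0,
                           seed=10, filter_sd=10.0)
        curve = autocorrelation_divergence(trajs, [10, 40], t_min=0)
        assert curve.sigma_d[0] < curve.sigma_d[1]

    def test_too_few_pairs_omitted_with_warning(self):
        trajs = flat_trajs([10.0], n_frames=5)
        with pytest.warns(UserWarning):
            curve = autocorrelation_divergence(trajs, [40], t_min=0)
        assert curve.taus.size == 0


class TestNormalizedHistogram:
    def test_median_exactly_one(self):
        rng = np.random.default_rng(1)
        norm, _, _ = normalized_histogram(rng.lognormal(3, 0.8, 127))
        assert np.median(norm) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(3, 0.8, 127)
        n1, (c1, e1), cv1 = normalized_histogram(x, bin_edges=np.linspace(0, 6, 25))
        n2, (c2, e2), cv2 = normalized_histogram(7 * x, bin_edges=np.linspace(0, 6, 25))
        assert np.array_equal(c1, c2)
        assert cv1 == pytest.approx(cv2, rel=1e-9)

    def test_fixture_distribution_right_skewed_with_unit_cv(self):
        from luxtrace.fixtures import get_fixture
        from luxtrace.synthetic import draw_ensemble

        model = get_fixture("MJ11-single", seed=13).model_copy(update={"n_cells": 127})
        amps = np.array([p.amplitude for p in draw_ensemble(model, 1000.0)])
        norm, _, cv = normalized_histogram(amps)
        assert 0.8 <= cv <= 1.3
        assert norm.mean() > np.median(norm)      # right skew

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            normalized_histogram([-1.0, 0.0, 0.0])


def test_per_cell_level_averages_window():
    t = np.arange(0, 251, 10.0)
    raw = np.where(t <= 100, 0.0, 60.0)
    traj = Trajectory(0, t, raw, raw.copy(), 0.0)
    assert per_cell_level(traj, 100.0, 250.0) == pytest.approx(60.0)
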