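"""Order parameters: efficiency, Binder cumulant, transition diagnostics."""

import numpy as np
import pytest

from flock3d import ModelParams, SwarmState, efficiency, binder_cumulant, \
    transition_time, ensemble_histogram, EfficiencySeries

from conftest import random_rotation


def state_with_velocities(v):
    v = np.asarray(v, float)
    pos = np.full_like(v, 10.0)
    pos += np.arange(len(v))[:, None]  # distinct positions
    return SwarmState(0.0, pos, v)


class TestEfficiency:
    def test_perfect_alignment_is_one(self):
        p = ModelParams(N=3, L=50.0)
        st = state_with_velocities([[5.0, 0, 0]] * 3)
        assert efficiency(st, p) == pytest.approx(1.0)

    def test_cancellation_is_zero(self):
        p = ModelParams(N=2, L=50.0)
        st = state_with_velocities([[5.0, 0, 0], [-5.0, 0, 0]])
        assert efficiency(st, p) == pytest.approx(0.0)

    def test_right_angle_pair(self):
        p = ModelParams(N=2, L=50.0)
        st = state_with_velocities([[5.0, 0, 0], [0, 5.0, 0]])
        assert efficiency(st, p) == pytest.approx(np.sqrt(2) / 2)

    def test_can_exceed_one(self):
        p = ModelParams(N=2, L=50.0)
        st = state_with_velocities([[7.0, 0, 0], [7.0, 0, 0]])
        assert efficiency(st, p) == pytest.approx(1.4)

    def test_rotation_and_permutation_invariance(self, rng):
        p = ModelParams(N=10, L=50.0)
        v = rng.standard_normal((10, 3)) * 3
        e0 = efficiency(state_with_velocities(v), p)
        Q = random_rotation(rng)
        assert efficiency(state_with_velocities(v @ Q.T), p) == pytest.approx(e0)
        perm = rng.permutation(10)
        assert efficiency(state_with_velocities(v[perm]), p) == pytest.approx(e0)


class TestBinderCumulant:
    def test_equal_samples_two_thirds(self):
        assert binder_cumulant([0.37] * 10) == pytest.approx(2 / 3)

    def test_uniform_samples_approach_two_fifths(self):
        # <E^2> = 1/3, <E^4> = 1/5 for U(0,1): B -> 1 - (1/5)/(3/9) = 0.4
        u = np.random.default_rng(0).uniform(0, 1, 200_000)
        assert binder_cumulant(u) == pytest.approx(0.4, abs=0.005)

    def test_two_point_distribution(self):
        # {0, c} equally weighted: 1 - (c^4/2)/(3 (c^2/2)^2) = 1/3
        assert binder_cumulant([0.0, 0.8]) == pytest.approx(1 / 3)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.1, 1, 100)
        assert binder_cumulant(7.3 * x) == pytest.approx(binder_cumulant(x))

    def test_normalized_variant(self):
        assert binder_cumulant([0.5] * 4, N=100) == pytest.approx(2 / 3 / 100)

    def test_all_zero_undefined(self):
        with pytest.raises(ZeroDivisionError):
            binder_cumulant([0.0, 0.0])


class TestTransitionTime:
    def make(self, times, values):
        return EfficiencySeries(np.asarray(times, float),
                                np.asarray(values, float))

    def test_step_series(self):
        t = np.arange(0, 200.0, 10.0)
        v = np.where(t >= 100.0, 0.95, 0.05)
        s = self.make(t, v)
        assert transition_time(s, 0.8) == 100.0

    def test_never_crossing(self):
        s = self.make(np.arange(5.0), np.full(5, 0.05))
        assert transition_time(s, 0.8) is None

    def test_short_spike_filtered_by_dwell(self):
        t = np.arange(0, 100.0, 10.0)
        v = np.full_like(t, 0.1)
        v[4] = 0.95  # single-sample spike
        s = self.make(t, v)
        assert transition_time(s, 0.8, dwell=20.0) is None

    def test_dwell_met_then_reported(self):
        t = np.arange(0, 100.0, 10.0)
        v = np.where(t >= 30.0, 0.9, 0.1)
        s = self.make(t, v)
        assert transition_time(s, 0.8, dwell=30.0) == 30.0

    def test_invalid_threshold(self):
        s = self.make([0.0, 1.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            transition_time(s, 1.5)


class TestEnsembleHistogram:
    def cadence(self, n=64, dt=10.0):
        return np.arange(n) * dt

    def test_identical_runs_single_bin(self):
        t = self.cadence()
        runs = [EfficiencySeries(t, np.full_like(t, 0.555)) for _ in range(10)]
        summ = ensemble_histogram(runs)
        assert summ.run_count == 10
        assert np.all(summ.counts.sum(axis=1) == 10)
        assert np.all((summ.counts > 0).sum(axis=1) == 1)

    def test_counts_sum_to_run_count(self):
        rng = np.random.default_rng(3)
        t = self.cadence()
        runs = [EfficiencySeries(t, rng.uniform(0, 1, len(t)))
                for _ in range(25)]
        summ = ensemble_histogram(runs)
        assert np.all(summ.counts.sum(axis=1) == 25)

    def test_adjacent_bins_resolved(self):
        t = self.cadence()
        runs = [EfficiencySeries(t, np.full_like(t, 0.005)),
                EfficiencySeries(t, np.full_like(t, 0.015))]
        summ = ensemble_histogram(runs)
        row = summ.counts[0]
        occupied = np.flatnonzero(row)
        assert list(occupied) == [0, 1]  # bins [0, 0.01) and [0.01, 0.02)

    def test_ratio_spaced_time_grid(self):
        t = np.arange(1024.0)
        runs = [EfficiencySeries(t, np.linspace(0, 0.9, len(t)))]
        summ = ensemble_histogram(runs, time_ratio=2.0)
        ratios = summ.time_bins[2:] / summ.time_bins[1:-1]
        assert np.all(ratios >= 2.0 - 1e-9)

    def test_inconsistent_cadence_rejected(self):
        a = EfficiencySeries(np.arange(5.0), np.zeros(5) + 0.1)
        b = EfficiencySeries(np.arange(6.0), np.zeros(6) + 0.1)
        with pytest.raises(ValueError):
            ensemble_histogram([a, b])

    def test_binder_series_matches_direct_evaluation(self):
        rng = np.random.default_rng(9)
        t = self.cadence()
        runs = [EfficiencySeries(t, rng.uniform(0.2, 1.0, len(t)))
                for _ in range(30)]
        summ = ensemble_histogram(runs)
        vals = np.stack([r.values for r in runs])
        # recompute at the first selected time bin
        i = np.flatnonzero(np.isclose(t, summ.time_bins[0]))[0]
        assert summ.binder[0] == pytest.approx(binder_cumulant(vals[:, i]))


class TestSeriesValidation:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError):
            EfficiencySeries([0.0, 0.0], [0.1, 0.1])

    def test_tail_mean(self):
        s = EfficiencySeries(np.arange(0, 101.0), np.arange(0, 101.0) / 100)
        assert s.tail_mean(0.1) == pytest.approx(np.mean(np.arange(90, 101)) / 100)
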