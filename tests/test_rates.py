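"""Firing-rate estimation: Gaussian-kernel properties, averaging, response
characteristics, the coefficient of determination, and segment extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ornsim as o


def make_train(times, duration):
    return o.SpikeTrain(np.asarray(times, dtype=float), duration)


class TestKernelRate:
    def test_no_spikes_zero(self):
        grid = o.rate_grid(0, 1, 0.001)
        rate = o.kernel_rate(make_train([], 1.0), grid)
        assert np.all(rate.rate == 0)

    def test_single_spike_peak_value(self):
        # Gaussian density maximum: 1/(sqrt(2*pi)*0.03) ~ 13.298 Hz
        grid = o.rate_grid(0, 1, 0.001)
        rate = o.kernel_rate(make_train([0.5], 1.0), grid)
        i = np.argmax(rate.rate)
        assert grid[i] == pytest.approx(0.5)
        assert rate.rate[i] == pytest.approx(13.298, abs=1e-3)

    def test_integral_equals_spike_count(self):
        grid = o.rate_grid(0, 2, 0.001)  # extends >5 sd beyond all spikes
        spikes = make_train([0.5, 0.9, 1.0, 1.4], 2.0)
        rate = o.kernel_rate(spikes, grid)
        assert rate.integral() == pytest.approx(4.0, rel=1e-3)

    @given(
        t1=st.lists(st.floats(0.3, 0.7), min_size=1, max_size=5, unique=True),
        t2=st.lists(st.floats(0.3, 0.7), min_size=1, max_size=5, unique=True),
    )
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_spike_trains(self, t1, t2):
        # rate of a merged train equals the sum of the individual rates
        grid = o.rate_grid(0, 1, 0.002)
        merged = np.unique(np.concatenate([t1, t2]))
        r_merged = o.kernel_rate(np.array(merged), grid).rate
        r_sum = o.kernel_rate(np.array(t1), grid).rate + o.kernel_rate(
            np.array(t2), grid
        ).rate
        dupes = len(t1) + len(t2) - len(merged)
        if dupes == 0:
            np.testing.assert_allclose(r_merged, r_sum, atol=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            o.kernel_rate(make_train([0.1], 1.0), np.array([]))

    def test_bad_sd_rejected(self):
        with pytest.raises(ValueError):
            o.kernel_rate(make_train([0.1], 1.0), o.rate_grid(0, 1), sd=0.0)


class TestAverageRate:
    def test_identical_inputs(self):
        grid = o.rate_grid(0, 1, 0.01)
        tr = o.kernel_rate(make_train([0.5], 1.0), grid)
        mean, lq, uq = o.average_rate([tr, tr, tr])
        np.testing.assert_allclose(mean.rate, tr.rate)
        np.testing.assert_allclose(uq.rate - lq.rate, 0.0, atol=1e-12)

    def test_two_constant_traces(self):
        grid = o.rate_grid(0, 1, 0.01)
        t0 = o.RateTrace(grid, np.zeros(grid.size))
        t10 = o.RateTrace(grid, np.full(grid.size, 10.0))
        mean, _, _ = o.average_rate([t0, t10])
        np.testing.assert_allclose(mean.rate, 5.0)

    def test_quartiles_match_sort_oracle(self):
        grid = o.rate_grid(0, 0.1, 0.05)
        consts = [3.0, 1.0, 4.0, 1.5, 9.0]
        traces = [o.RateTrace(grid, np.full(grid.size, c)) for c in consts]
        _, lq, uq = o.average_rate(traces)
        assert lq.rate[0] == pytest.approx(np.percentile(consts, 25))
        assert uq.rate[0] == pytest.approx(np.percentile(consts, 75))

    def test_mismatched_grids_rejected(self):
        a = o.RateTrace(o.rate_grid(0, 1, 0.01), np.zeros(101))
        b = o.RateTrace(o.rate_grid(0, 2, 0.02), np.zeros(101))
        with pytest.raises(ValueError, match="grid"):
            o.average_rate([a, b])


class TestResponseCharacteristics:
    def test_spike_at_onset_zero_latency(self):
        grid = o.rate_grid(0, 1, 0.001)
        spikes = make_train([0.5], 1.0)
        rate = o.kernel_rate(spikes, grid)
        _, _, lat = o.response_characteristics(rate, spikes, onset=0.5)
        assert lat == 0.0

    def test_monotone_trace_peak_at_end(self):
        grid = o.rate_grid(0, 1, 0.01)
        rate = o.RateTrace(grid, np.linspace(0, 50, grid.size))
        _, peak_t, _ = o.response_characteristics(rate, make_train([], 1.0), 0.2)
        assert peak_t == grid[-1]

    def test_model_peak_near_100ms_after_onset(self, pulse_response_100pg):
        # adaptive model, 100 pg pulse: transient peak ~100 ms after onset
        spikes, _, _ = pulse_response_100pg
        rate = o.kernel_rate(spikes, o.rate_grid(0, 1.5, 0.001))
        _, peak_t, _ = o.response_characteristics(rate, spikes, onset=0.5)
        assert 0.05 < peak_t - 0.5 < 0.15

    def test_onset_outside_grid_rejected(self):
        grid = o.rate_grid(0, 1, 0.01)
        rate = o.RateTrace(grid, np.zeros(grid.size))
        with pytest.raises(ValueError):
            o.response_characteristics(rate, make_train([], 1.0), 2.0)


class TestRSquared:
    @pytest.fixture
    def f_d(self):
        grid = o.rate_grid(0, 1, 0.001)
        return o.kernel_rate(make_train([0.2, 0.5, 0.6], 1.0), grid)

    def test_perfect_match(self, f_d):
        assert o.r_squared(f_d, f_d) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, f_d):
        mean = np.trapezoid(f_d.rate, f_d.time) / (f_d.time[-1] - f_d.time[0])
        f_m = o.RateTrace(f_d.time, np.full(f_d.time.size, mean))
        assert o.r_squared(f_d, f_m) == pytest.approx(0.0, abs=1e-9)

    def test_amplified_deviation_closed_forms(self, f_d):
        # f_m = mean + a*(f_d - mean) gives f_d - f_m = (1-a)(f_d - mean),
        # hence R^2 = 1 - (a-1)^2: a = 2 scores 0, a = 3 scores -3.  A
        # baseline offset keeps the amplified deviations non-negative.
        base = o.RateTrace(f_d.time, f_d.rate + 30.0)
        mean = np.trapezoid(base.rate, base.time) / (base.time[-1] - base.time[0])
        f_m2 = o.RateTrace(base.time, mean + 2 * (base.rate - mean))
        f_m3 = o.RateTrace(base.time, mean + 3 * (base.rate - mean))
        assert o.r_squared(base, f_m2) == pytest.approx(0.0, abs=1e-9)
        assert o.r_squared(base, f_m3) == pytest.approx(-3.0, rel=1e-9)

    def test_time_shift_invariance(self, f_d):
        shifted_d = o.RateTrace(f_d.time + 5.0, f_d.rate)
        noise = o.RateTrace(f_d.time, f_d.rate * 0.9)
        shifted_m = o.RateTrace(f_d.time + 5.0, f_d.rate * 0.9)
        assert o.r_squared(shifted_d, shifted_m) == pytest.approx(
            o.r_squared(f_d, noise), rel=1e-9
        )

    def test_constant_data_undefined(self):
        grid = o.rate_grid(0, 1, 0.01)
        const = o.RateTrace(grid, np.full(grid.size, 5.0))
        with pytest.raises(ZeroDivisionError):
            o.r_squared(const, const)


class TestSegments:
    def _stim_from_bins(self, bins, bin_s=0.1, dt=0.001, L=1e-5):
        valve = np.repeat(np.asarray(bins, float), int(round(bin_s / dt)))
        valve = np.concatenate([valve, valve[-1:]])
        t = np.arange(valve.size) * dt
        return o.StimulusTrace(t, L * valve, valve=valve)

    def test_single_qualifying_puff(self):
        # 0.2 s blank then 0.6 s puff -> exactly one segment
        stim = self._stim_from_bins([0, 0] + [1] * 6 + [0, 0])
        spikes = make_train([0.25, 0.5], 1.0)
        segs = o.extract_response_segments(stim, spikes)
        assert len(segs) == 1
        assert segs[0].onset == pytest.approx(0.2)
        assert segs[0].puff_s == pytest.approx(0.6)
        np.testing.assert_allclose(segs[0].spike_times_rel_onset, [0.05, 0.3])

    def test_short_puff_rejected(self):
        stim = self._stim_from_bins([0, 0] + [1] * 4 + [0, 0])  # 0.4 s puff
        segs = o.extract_response_segments(stim, make_train([], 0.8))
        assert segs == []

    def test_short_preceding_blank_rejected(self):
        stim = self._stim_from_bins([1] * 3 + [0] + [1] * 6, bin_s=0.05)
        # blank is only 0.05 s < 0.1 s
        segs = o.extract_response_segments(stim, make_train([], 0.5))
        assert segs == []

    def test_crafted_sequence_matches_hand_count(self):
        # hand-enumerated: puffs of 6, 3, 4, 5, 8 bins with preceding blanks
        # of 2, 1, 3, 1, 2 bins (0.1 s bins); qualifying = puff >= 0.5 s
        # after blank >= 0.1 s
        bins = (
            [0, 0] + [1] * 6 + [0] + [1] * 3 + [0, 0, 0] + [1] * 4
            + [0] + [1] * 5 + [0, 0] + [1] * 8
        )
        stim = self._stim_from_bins(bins)
        segs = o.extract_response_segments(stim, make_train([], len(bins) * 0.1))
        # qualifying: the 6-bin puff (blank 2), the 5-bin puff (blank 1),
        # and the trailing 8-bin puff (blank 2); the 3-bin and 4-bin puffs
        # are too short
        assert len(segs) == 3
        assert [round(s.puff_s, 3) for s in segs] == [0.6, 0.5, 0.8]

    def test_requires_valve_channel(self):
        stim = o.StimulusTrace(np.arange(100) * 0.01, np.zeros(100))
        with pytest.raises(ValueError, match="valve"):
            o.extract_response_segments(stim, make_train([], 1.0))
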