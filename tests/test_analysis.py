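import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechspike import (
    InvalidArgumentError,
    SpikeTrain,
    Trace,
    UndefinedStatisticError,
    detect_bursts,
    ibi,
    ibi_stats,
    isi,
    isi_stats,
    phase_plane,
    relative_error,
    spike_time_diffs,
)


def train(times, t_end=1000.0):
    return SpikeTrain(np.asarray(times, dtype=float), t_end)


class TestISI:
    def test_regular_train(self):
        stats = isi_stats(train([100, 150, 200]))
        assert stats.mean == 50 and stats.variance == 0 and stats.n == 2

    def test_unbiased_variance(self):
        stats = isi_stats(train([0, 10, 30]))
        assert stats.mean == 15
        assert stats.variance == 50  # ((-5)^2 + 5^2) / (2 - 1)

    def test_single_spike_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            isi(train([5]))
        with pytest.raises(UndefinedStatisticError):
            isi_stats(train([5, 10]))  # variance needs 3 spikes

    def test_intervals_are_consecutive_differences(self):
        assert np.array_equal(isi(train([1, 4, 9, 16])), [3, 5, 7])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 50), min_size=3, max_size=30), st.floats(0, 500))
    def test_translation_invariance(self, gaps, shift):
        times = np.cumsum(gaps)
        a = isi_stats(train(times, times[-1] + 1))
        b = isi_stats(train(times + shift, times[-1] + shift + 1))
        assert a.mean == pytest.approx(b.mean)
        assert a.variance == pytest.approx(b.variance, abs=1e-8)
        assert (np.diff(times) >= 0).all()

    def test_strictly_increasing_enforced(self):
        with pytest.raises(InvalidArgumentError):
            train([10, 10, 20])


class TestBursts:
    def test_two_bursts(self):
        bursts = detect_bursts(train([10, 12, 14, 200, 202, 204]), 20)
        assert len(bursts) == 2
        assert np.array_equal(ibi(bursts), [190])

    def test_isolated_spikes_are_one_spike_bursts(self):
        bursts = detect_bursts(train([10, 100, 190]), 20)
        assert [len(b) for b in bursts] == [1, 1, 1]
        assert np.array_equal(ibi(bursts), [90, 90])

    def test_empty_train(self):
        assert detect_bursts(train([]), 20) == []

    def test_threshold_extremes(self):
        t = train([10, 30, 60, 100])
        assert len(detect_bursts(t, 5.0)) == 4  # below every ISI
        assert len(detect_bursts(t, 1e6)) == 1  # above the window

    def test_ibi_stats(self):
        bursts = detect_bursts(train([0, 2, 100, 102, 210, 212]), 20)
        stats = ibi_stats(bursts)
        assert stats.mean == 105 and stats.n == 2

    def test_too_few_bursts(self):
        with pytest.raises(UndefinedStatisticError):
            ibi_stats(detect_bursts(train([10, 12]), 20))


class TestRelativeError:
    @pytest.mark.parametrize("test,ref,expected", [
        (48.5, 48.6, 0.002),
        (45.0, 44.5, 0.011),
        (41.5, 41.2, 0.007),
        (39.0, 38.5, 0.012),  # 0.012987 truncates; rounding would give 0.013
    ])
    def test_published_error_column(self, test, ref, expected):
        assert relative_error(test, ref) == expected

    def test_identical_is_zero(self):
        assert relative_error(37.7, 37.7) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidArgumentError):
            relative_error(1.0, 0.0)


class TestPhasePlane:
    def test_pairs_and_bookkeeping(self):
        tr = Trace(values=np.array([1.0, 2, 3, 4]), dt=1.0, unit="mV")
        pairs = phase_plane(tr, tau=1.0)
        assert pairs.tolist() == [[1, 2], [2, 3], [3, 4]]
        assert pairs.shape[0] == len(tr) - 1

    def test_constant_trace_on_diagonal(self):
        tr = Trace(values=np.full(20, -65.0), dt=0.5, unit="mV")
        pairs = phase_plane(tr, tau=2.0)
        assert np.array_equal(pairs[:, 0], pairs[:, 1])
        assert pairs.shape[0] == 20 - 4

    def test_non_multiple_tau_rejected(self):
        tr = Trace(values=np.zeros(10), dt=0.01, unit="mV")
        with pytest.raises(InvalidArgumentError):
            phase_plane(tr, tau=0.015)

    def test_periodic_steady_state_closes_a_loop(self, spiking_params):
        # successive steady-state cycles trace the same closed curve in the
        # (v(t), v(t+tau)) plane: every (subsampled) point of the last cycle
        # lies close to some point of the cycle before it
        from mechspike import make_constant, simulate_euler

        current = make_constant(2.4 * 4.4, 500.0, 0.01)
        result = simulate_euler(current, spiking_params)
        pairs = phase_plane(result.v_trace, tau=5.0)
        spikes = result.spike_times
        idx = lambda t: round(t / 0.01)
        prev = pairs[idx(spikes[-4]): idx(spikes[-3])]
        last = pairs[idx(spikes[-3]): idx(spikes[-2])][::25]
        dists = np.sqrt(
            ((last[:, None, :] - prev[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        assert dists.max() < 1.0  # mV


class TestSpikeTimeDiffs:
    def test_offsets_and_max(self):
        cmp = spike_time_diffs(train([10, 20]), train([10.1, 20.2]))
        assert cmp.matched
        assert np.allclose(cmp.offsets, [0.1, 0.2])
        assert cmp.max_abs_offset == pytest.approx(0.2)

    def test_identical_trains(self):
        cmp = spike_time_diffs(train([1, 2, 3]), train([1, 2, 3]))
        assert cmp.max_abs_offset == 0.0

    def test_count_mismatch_reported_not_raised(self):
        cmp = spike_time_diffs(train([1, 2, 3]), train([1, 2, 3, 4]))
        assert not cmp.matched
        assert (cmp.n_a, cmp.n_b) == (3, 4)
        assert cmp.offsets is None
        assert "mismatch" in str(cmp)
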