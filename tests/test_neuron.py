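import numpy as np
import pytest

from mechspike import (
    InvalidArgumentError,
    NeuronParams,
    NeuronState,
    apply_reset,
    default_init,
    detect_bursts,
    euler_step,
    isi_stats,
    make_constant,
    make_staircase,
    simulate_euler,
    simulate_rk4,
    steady_state_isi_mean,
)

REST = NeuronState(-70.0, -14.0)  # analytic fixed point at I = 0


class TestParamsAndInit:
    def test_spiking_preset(self, spiking_params):
        p = spiking_params
        assert (p.a, p.b, p.c, p.d) == (0.02, 0.2, -65.0, 6.0)
        assert p.vth == 30.0 and p.cm == 1.0

    def test_bursting_preset(self, bursting_params):
        p = bursting_params
        assert (p.c, p.d) == (-50.0, 1.5)

    def test_unknown_regime(self):
        with pytest.raises(InvalidArgumentError):
            NeuronParams.preset("chattering")

    def test_default_init_on_nullcline(self, spiking_params, bursting_params):
        assert default_init(spiking_params) == (-65.0, -13.0)
        assert default_init(bursting_params) == (-50.0, -10.0)
        p = NeuronParams(b=0.37, c=-55.0)
        v, u = default_init(p)
        assert u / v == pytest.approx(0.37)


class TestEulerStep:
    def test_rest_state_is_stationary(self, spiking_params):
        new = euler_step(REST, 0.0, 0.0, spiking_params, h=0.01)
        assert new.v == pytest.approx(-70.0, abs=1e-12)
        assert new.u == pytest.approx(-14.0, abs=1e-12)

    def test_origin_moves_by_h_times_140(self, spiking_params):
        new = euler_step(NeuronState(0.0, 0.0), 0.0, 0.0, spiking_params, h=0.01)
        assert new == (pytest.approx(1.4), 0.0)

    def test_constant_current_invisible_to_fa1(self, spiking_params):
        new = euler_step(REST, 123.4, 0.0, spiking_params, h=0.01, afferent="FA-I")
        assert new.v == pytest.approx(-70.0, abs=1e-12)

    def test_nonpositive_h_rejected(self, spiking_params):
        with pytest.raises(InvalidArgumentError):
            euler_step(REST, 0.0, 0.0, spiking_params, h=0.0)


class TestReset:
    def test_above_threshold_resets(self, spiking_params):
        state, spiked = apply_reset(NeuronState(31.0, -10.0), spiking_params)
        assert spiked and state == (-65.0, -4.0)

    def test_below_threshold_unchanged(self, spiking_params):
        state, spiked = apply_reset(NeuronState(29.9, 0.0), spiking_params)
        assert not spiked and state == (29.9, 0.0)

    def test_boundary_included(self, bursting_params):
        state, spiked = apply_reset(NeuronState(30.0, 0.0), bursting_params)
        assert spiked and state == (-50.0, 1.5)


class TestSimulate:
    def test_zero_current_never_spikes(self, spiking_params):
        current = make_constant(0.0, 1000.0, 0.01)
        result = simulate_euler(current, spiking_params)
        assert result.spike_times.size == 0
        # trajectory settles toward the stable equilibrium near v = -70
        assert result.v_trace.values[-1] == pytest.approx(-70.0, abs=1.0)

    @pytest.mark.parametrize("simulate", [simulate_euler, simulate_rk4])
    def test_rest_point_stationary_over_long_run(self, simulate, spiking_params):
        current = make_constant(0.0, 1000.0, 0.01)  # 1e5 steps
        result = simulate(current, spiking_params, init=REST)
        assert np.max(np.abs(result.v_trace.values + 70.0)) < 1e-8
        assert np.max(np.abs(result.u_trace.values + 14.0)) < 1e-8

    def test_spike_samples_clamped_and_reset_stored(self, spiking_params):
        current = make_constant(12.0, 500.0, 0.01)
        result = simulate_euler(current, spiking_params)
        assert result.spike_times.size > 3
        v = result.v_trace.values
        idx = np.round((result.spike_times - current.t0) / current.dt).astype(int)
        assert np.all(v[idx] == spiking_params.vth)
        assert np.all(v[idx + 1] == spiking_params.c)  # reset write next sample
        assert np.all(np.diff(result.spike_times) > 0)
        assert v.max() == spiking_params.vth

    def test_spike_count_equals_reset_events(self, spiking_params):
        current = make_constant(12.0, 500.0, 0.01)
        result = simulate_euler(current, spiking_params)
        v = result.v_trace.values
        assert result.spike_times.size == np.count_nonzero(v == spiking_params.vth)

    def test_sa1_fires_throughout_sustained_stimulus(self, spiking_params):
        current = make_constant(2.4 * 4.4, 2000.0, 0.01)
        result = simulate_euler(current, spiking_params)
        spikes = result.spike_times
        for start in range(0, 2000, 200):
            assert ((spikes >= start) & (spikes < start + 200)).any(), (
                f"no spike in window [{start}, {start + 200}) ms"
            )

    @pytest.mark.parametrize("simulate", [simulate_euler, simulate_rk4])
    @pytest.mark.parametrize("height", [5.0, 10.0, 20.0])
    def test_fa1_step_and_hold_is_transient(self, simulate, spiking_params, height):
        current = make_staircase([(0.0, 100.0), (height, 900.0)], 0.01, unit="mA")
        result = simulate(current, spiking_params, afferent="FA-I")
        assert not (result.spike_times > 300.0).any()

    def test_fa1_responds_at_onset(self, spiking_params):
        current = make_staircase([(0.0, 100.0), (10.0, 400.0)], 0.01, unit="mA")
        result = simulate_euler(current, spiking_params, afferent="FA-I")
        assert result.spike_times.size >= 1
        assert np.all(np.abs(result.spike_times - 100.0) < 200.0)

    def test_isi_regularity_in_spiking_regime(self, spiking_params):
        current = make_constant(2.6 * 4.4, 1000.0, 0.01)
        result = simulate_euler(current, spiking_params)
        stats = isi_stats(result.spike_train.after(500.0))
        assert stats.variance < 0.01  # ms^2

    def test_bursting_regime_emits_multi_spike_bursts(
        self, spiking_params, bursting_params
    ):
        current = make_constant(2.6 * 4.4, 1000.0, 0.01)
        bursting = simulate_euler(current, bursting_params)
        bursts = detect_bursts(bursting.spike_train)
        assert max(len(b) for b in bursts) >= 2
        spiking = simulate_euler(current, spiking_params)
        assert max(len(b) for b in detect_bursts(spiking.spike_train)) == 1


class TestRateCoding:
    def test_isi_strictly_decreasing_in_amplitude(self, sweep_results):
        for backend in ("euler", "rk4"):
            isis = [sweep_results[amp][backend] for amp in sorted(sweep_results)]
            assert all(a > b for a, b in zip(isis, isis[1:])), (backend, isis)

    def test_euler_matches_rk4_within_one_percent(self, sweep_results, spiking_params):
        # grid-refinement oracle: halving h changes the RK4 ISI by < 0.1%,
        # so the dt = 0.01 ms reference is converged before comparing
        coarse = sweep_results[2.6]["rk4"]
        fine = steady_state_isi_mean(
            simulate_rk4(
                make_constant(2.6 * 4.4, 1000.0, 0.005), spiking_params
            ).spike_train
        )
        assert abs(fine - coarse) / coarse < 1e-3
        for amp, isis in sweep_results.items():
            assert abs(isis["euler"] - isis["rk4"]) / isis["rk4"] < 0.01
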