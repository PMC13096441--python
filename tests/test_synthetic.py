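"""Generator correctness: determinism, partitions, rate calibration and
ground-truth bookkeeping, checked against simple probabilistic oracles."""

import numpy as np
import pytest

from twitchlab.errors import InvalidParameterError
from twitchlab.synthetic import (
    NeuronSpec,
    ResponseKernel,
    SimulationParams,
    realize_kernel,
    rate_on_grid,
    simulate_frame_clock,
    simulate_movement_events,
    simulate_pixel_change_series,
    simulate_session,
    simulate_spike_train,
    simulate_state_timeline,
    simulate_trajectory,
    GroundTruth,
)
from twitchlab.types import MovementEvent, StateTimeline


def wake_only_params(duration, **kw):
    return SimulationParams(
        session_duration=duration,
        state_mean_durations={"quiet_wake": duration}, **kw,
    )


class TestParams:
    def test_zero_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationParams(session_duration=0.0)

    @pytest.mark.parametrize("bad", [{"twitch_rate": -1.0}, {"dropped_frame_prob": 1.0}])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            SimulationParams(**bad)

    def test_premove_fraction_bounds(self):
        with pytest.raises(InvalidParameterError):
            ResponseKernel(premove_fraction=1.5)


class TestKernel:
    @pytest.mark.parametrize(
        "latency,sigma,premove",
        [(15, 45, 0.45), (34, 45, 0.29), (100, 150, 0.14), (100, 150, 0.07), (30, 20, 0.1)],
    )
    def test_premove_mass_and_mode(self, latency, sigma, premove):
        dist = realize_kernel(ResponseKernel(latency, sigma, 5.0, premove))
        assert dist.cdf(0.0) == pytest.approx(premove, abs=1e-4)
        xs = np.linspace(-5 * sigma / 1000, latency / 1000 + 5 * sigma / 1000, 20001)
        mode = xs[np.argmax(dist.pdf(xs))]
        assert mode * 1000 == pytest.approx(latency, abs=0.5)

    def test_infeasible_premove_raises(self):
        # a kernel peaked 100 ms after onset with 10 ms scale cannot put
        # 40% of its mass before onset
        with pytest.raises(InvalidParameterError):
            realize_kernel(ResponseKernel(100, 10, 5.0, 0.4))


class TestStateTimeline:
    def test_partition_and_interval_count(self):
        params = SimulationParams(
            session_duration=3600.0,
            state_mean_durations={"NREM": 60.0, "REM": 60.0, "quiet_wake": 60.0},
            seed=1,
        )
        tl = simulate_state_timeline(params)
        starts = [s for s, _, _ in tl.intervals]
        ends = [e for _, e, _ in tl.intervals]
        assert starts[0] == 0.0 and ends[-1] == 3600.0
        np.testing.assert_allclose(starts[1:], ends[:-1])
        # ~3600/60 = 60 exponential dwells; allow broad sampling tolerance
        assert 30 <= len(tl.intervals) <= 110

    def test_single_state_covers_whole_session(self):
        tl = simulate_state_timeline(wake_only_params(500.0))
        assert tl.intervals == [(0.0, 500.0, "quiet_wake")]

    def test_resimulation_with_same_seed_identical(self):
        params = SimulationParams(session_duration=1000.0, seed=7)
        a = simulate_state_timeline(params)
        b = simulate_state_timeline(params)
        assert a.intervals == b.intervals


class TestMovementEvents:
    def test_no_rem_means_no_twitches(self):
        tl = simulate_state_timeline(wake_only_params(300.0))
        events = simulate_movement_events(tl, wake_only_params(300.0))
        assert all(e.movement_class == "wake" for e in events)

    def test_twitch_count_within_poisson_bounds(self):
        params = SimulationParams(
            session_duration=1000.0,
            state_mean_durations={"REM": 1000.0}, twitch_rate=0.5,
            twitch_body_parts=("forelimb",), seed=2,
        )
        tl = StateTimeline([(0.0, 1000.0, "REM")])
        events = simulate_movement_events(tl, params)
        n = len([e for e in events if e.movement_class == "twitch"])
        lam = 0.5 * 1000.0
        assert abs(n - lam) <= 3 * np.sqrt(lam)

    def test_twitches_only_in_rem(self):
        params = SimulationParams(session_duration=1200.0, seed=3)
        tl = simulate_state_timeline(params)
        for e in simulate_movement_events(tl, params):
            state = tl.state_at(e.onset)
            if e.movement_class == "twitch":
                assert state == "REM"
            else:
                assert state in ("quiet_wake", "active_wake")

    def test_wake_onsets_at_least_quiescence_apart(self):
        params = wake_only_params(500.0, wake_move_rate=5.0, seed=4)
        tl = simulate_state_timeline(params)
        onsets = [e.onset for e in simulate_movement_events(tl, params)]
        assert len(onsets) > 100
        assert np.min(np.diff(onsets)) >= 0.5


class TestSpikeTrain:
    def test_zero_gain_is_homogeneous_baseline(self):
        params = wake_only_params(
            500.0, baseline_rate={"wake": 10.0},
            response_kernel=ResponseKernel(gain=0.0), seed=5,
        )
        tl = simulate_state_timeline(params)
        events = simulate_movement_events(tl, params)
        train = simulate_spike_train(events, tl, params)
        rate = train.n_spikes / 500.0
        assert abs(rate - 10.0) <= 3 * np.sqrt(10.0 * 500.0) / 500.0

    def test_state_dependent_rates_recovered(self):
        # REM vs wake baseline rates used as realistic parameter values
        params = SimulationParams(
            session_duration=1000.0,
            state_mean_durations={"REM": 500.0, "quiet_wake": 500.0},
            baseline_rate={"REM": 13.1, "wake": 7.2},
            response_kernel=ResponseKernel(gain=0.0), seed=3,
        )
        tl = StateTimeline([(0.0, 500.0, "REM"), (500.0, 1000.0, "quiet_wake")])
        train = simulate_spike_train([], tl, params)
        t = train.spike_times
        for lo, hi, expect in [(0, 500, 13.1), (500, 1000, 7.2)]:
            n = np.sum((t >= lo) & (t < hi))
            assert abs(n / 500.0 - expect) <= 3 * np.sqrt(expect * 500) / 500

    def test_event_triggered_average_peaks_at_latency(self):
        kernel = ResponseKernel(latency_ms=30, sigma_ms=12, gain=20.0, premove_fraction=0.005)
        duration = 1500.0
        params = wake_only_params(
            duration, baseline_rate={"wake": 2.0}, response_kernel=kernel,
            wake_move_rate=0.25, seed=6,
        )
        tl = simulate_state_timeline(params)
        events = simulate_movement_events(tl, params)
        assert len(events) >= 300
        # oracle: the generator's own rate function, event-triggered
        t, rate = rate_on_grid(events, tl, params)
        lags = np.arange(-0.1, 0.1, 0.001)
        eta = np.zeros(lags.size)
        for e in events:
            idx = np.searchsorted(t, e.onset + lags)
            idx = np.clip(idx, 0, t.size - 1)
            eta += rate[idx]
        oracle_peak = lags[np.argmax(eta)] * 1000
        assert oracle_peak == pytest.approx(30, abs=2)
        # the spike draw reproduces the oracle's peak within one 10 ms bin
        train = simulate_spike_train(events, tl, params)
        onsets = np.array([e.onset for e in events])
        rel = train.spike_times[None, :] - onsets[:, None]
        hist, edges = np.histogram(rel.ravel(), bins=np.arange(-0.1, 0.11, 0.01))
        centers = (edges[:-1] + edges[1:]) / 2
        assert abs(centers[np.argmax(hist)] * 1000 - 30) <= 10

    def test_negative_rate_rejected(self):
        params = wake_only_params(100.0)
        tl = simulate_state_timeline(params)
        bad = NeuronSpec("x", baseline_rate={"wake": -1.0})
        with pytest.raises(InvalidParameterError):
            simulate_spike_train([], tl, params, neuron=bad)


class TestTrajectory:
    def test_zero_events_stays_within_noise(self):
        params = wake_only_params(10.0, trajectory_noise_px=0.2, seed=8)
        traj = simulate_trajectory([], params, duration=10.0)
        assert np.abs(traj.x - 360.0).max() < 1.5  # ~7 sigma bound
        assert np.all((traj.likelihood >= 0) & (traj.likelihood <= 1))

    def test_single_event_peak_displacement_up(self):
        # 10 mm at 90 deg (up) -> 57.5 px straight "up" = decreasing image y
        params = wake_only_params(5.0, trajectory_noise_px=0.0)
        ev = MovementEvent(onset=1.0, body_part="forelimb", movement_class="twitch",
                           amplitude_mm=10.0, angle_deg=90.0)
        traj = simulate_trajectory([ev], params, duration=5.0)
        disp_y = 270.0 - traj.y
        assert disp_y.max() == pytest.approx(10.0 * 5.75, rel=0.01)
        assert np.abs(traj.x - 360.0).max() < 1e-9

    def test_degenerate_von_mises_fixes_angle(self):
        params = wake_only_params(
            600.0, angle_distribution={"mu_deg": 129.0, "kappa": np.inf},
            wake_move_rate=0.1, seed=9,
        )
        tl = simulate_state_timeline(params)
        events = simulate_movement_events(tl, params)
        assert len(events) > 10
        assert all(e.angle_deg == pytest.approx(129.0) for e in events)


class TestPixelSeries:
    def test_no_events_zero_noise_all_zero(self):
        params = wake_only_params(5.0, pixel_noise_lambda=0.0)
        series = simulate_pixel_change_series([], params, duration=5.0)
        assert np.all(series.values == 0)

    def test_onset_frame_index(self):
        params = wake_only_params(5.0, pixel_noise_lambda=0.0)
        ev = MovementEvent(onset=1.00, body_part="forelimb", movement_class="twitch")
        series = simulate_pixel_change_series([ev], params, duration=5.0)
        assert np.flatnonzero(series.values)[0] == 100

    def test_close_events_bookkept_as_merged_pulse(self):
        params = wake_only_params(5.0, pixel_noise_lambda=0.0)
        evs = [
            MovementEvent(onset=1.00, body_part="forelimb", movement_class="twitch"),
            MovementEvent(onset=1.05, body_part="forelimb", movement_class="twitch"),
        ]
        gt = GroundTruth()
        simulate_pixel_change_series(evs, params, duration=5.0, roi_label="forelimb",
                                     ground_truth=gt)
        # 50 ms apart with 50 ms pulses: exactly one merged pulse recorded
        assert gt.pixel_pulses["forelimb"] == [(100, 110)]


class TestFrameClock:
    def test_no_drops_exact_interpulse_counts(self):
        params = wake_only_params(60.0)  # 100 fps, 3 s pulses
        clock = simulate_frame_clock(params, duration=60.0)
        idx = np.searchsorted(clock.frame_times, clock.pulse_times)
        assert np.all(np.diff(idx) == 300)

    def test_drop_count_within_binomial_bounds(self):
        params = wake_only_params(60.0, dropped_frame_prob=0.001, seed=4)
        gt = GroundTruth()
        clock = simulate_frame_clock(params, duration=60.0, ground_truth=gt)
        n_dropped = gt.dropped_frame_indices.size
        assert clock.n_frames == 6000 - n_dropped
        # Binomial(6000, 0.001): mean 6, 3 sigma ~ 7.3
        assert abs(n_dropped - 6.0) <= 3 * np.sqrt(6000 * 0.001 * 0.999)


class TestSessionDeterminism:
    def test_same_seed_bit_identical(self):
        params = SimulationParams(session_duration=120.0, seed=42)
        a = simulate_session(params)
        b = simulate_session(params)
        assert a.timeline.intervals == b.timeline.intervals
        assert [e.onset for e in a.events] == [e.onset for e in b.events]
        for ta, tb in zip(a.spike_trains, b.spike_trains):
            np.testing.assert_array_equal(ta.spike_times, tb.spike_times)
        np.testing.assert_array_equal(a.trajectory.x, b.trajectory.x)
        np.testing.assert_array_equal(
            a.pixel_series["whole_body"].values, b.pixel_series["whole_body"].values)

    def test_different_seed_differs(self):
        a = simulate_session(SimulationParams(session_duration=120.0, seed=1))
        b = simulate_session(SimulationParams(session_duration=120.0, seed=2))
        assert not np.array_equal(
            a.spike_trains[0].spike_times, b.spike_trains[0].spike_times)

    def test_ground_truth_events_map_one_to_one(self, fixture_session):
        gt = fixture_session.ground_truth
        assert gt.events is fixture_session.events
        onsets = [e.onset for e in gt.events]
        assert len(onsets) == len(set(onsets))
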