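"""Kinematics extraction and direction/amplitude selectivity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twitchlab.errors import InvalidParameterError
from twitchlab.kinematics import (
    amplitude_r_squared,
    classify_selectivity,
    compute_kinematics,
    compute_tuning,
    direction_eta_squared,
    spike_count_in_activity_window,
    split_preferred_movements,
)
from twitchlab.synthetic import (
    DirectionTuning,
    NeuronSpec,
    ResponseKernel,
    SimulationParams,
    simulate_movement_events,
    simulate_spike_train,
    simulate_state_timeline,
    simulate_trajectory,
)
from twitchlab.types import MovementEvent, SpikeTrain, Trajectory, TuningResult


def straight_trajectory(dx, dy_image, n=60, calibration=5.75):
    """Linear excursion from (0,0) to (dx, dy) and back, 100 fps."""
    t = np.arange(n) / 100.0
    prof = np.concatenate([np.linspace(0, 1, 15), np.linspace(1, 0, 15),
                           np.zeros(max(0, n - 30))])[:n]
    return Trajectory("forelimb", t, dx * prof, dy_image * prof,
                      np.ones(n), calibration)


class TestComputeKinematics:
    def test_pythagoras_and_angle(self):
        # peak at (3, 4) px image coords: amplitude 5 px = 0.8696 mm;
        # image y grows downward, so the math-convention angle is -53.13 deg
        traj = straight_trajectory(3.0, 4.0)
        kin = compute_kinematics(traj, 0.0, "twitch")
        assert kin.amplitude_mm == pytest.approx(5.0 / 5.75, abs=1e-4)
        assert kin.angle_deg == pytest.approx(360.0 - 53.13, abs=0.01)
        # an upward excursion (decreasing image y) reads 53.13 deg
        kin_up = compute_kinematics(straight_trajectory(3.0, -4.0), 0.0, "twitch")
        assert kin_up.angle_deg == pytest.approx(53.13, abs=0.01)

    def test_no_displacement_angle_undefined(self):
        traj = straight_trajectory(0.0, 0.0)
        kin = compute_kinematics(traj, 0.0, "twitch")
        assert kin.amplitude_mm == 0.0
        assert kin.angle_deg is None

    def test_gap_in_window_rejected(self):
        traj = straight_trajectory(3.0, 4.0, n=10)  # only 100 ms of frames
        with pytest.raises(InvalidParameterError):
            compute_kinematics(traj, 0.0, "wake")  # needs 500 ms

    def test_amplitude_invariant_to_translation_and_rotation(self):
        traj = straight_trajectory(3.0, 4.0)
        base = compute_kinematics(traj, 0.0, "twitch")
        # translate
        t2 = Trajectory("forelimb", traj.times, traj.x + 50, traj.y - 20,
                        traj.likelihood, traj.calibration)
        k2 = compute_kinematics(t2, 0.0, "twitch")
        assert k2.amplitude_mm == pytest.approx(base.amplitude_mm)
        # rotate by 90 deg in math convention (x, y_math) -> (-y_math, x)
        y_math = -traj.y
        x_r, y_r = -y_math, traj.x
        t3 = Trajectory("forelimb", traj.times, x_r, -y_r, traj.likelihood,
                        traj.calibration)
        k3 = compute_kinematics(t3, 0.0, "twitch")
        assert k3.amplitude_mm == pytest.approx(base.amplitude_mm)
        assert (k3.angle_deg - base.angle_deg) % 360 == pytest.approx(90.0, abs=1e-6)

    def test_class_mean_amplitudes_recovered(self):
        """Log-normal amplitude draws (class means 0.96 / 6.95 mm) come back
        through trajectory synthesis + kinematic extraction within 5%."""
        params = SimulationParams(
            session_duration=1500.0,
            state_mean_durations={"REM": 60.0, "quiet_wake": 60.0},
            twitch_rate=0.4, twitch_body_parts=("forelimb",),
            wake_move_rate=0.3, trajectory_noise_px=0.2, seed=29,
        )
        tl = simulate_state_timeline(params)
        events = simulate_movement_events(tl, params)
        traj = simulate_trajectory(events, params)
        got = {"twitch": [], "wake": []}
        for ev in events:
            try:
                kin = compute_kinematics(traj, ev.onset, ev.movement_class)
            except InvalidParameterError:
                continue
            got[ev.movement_class].append(kin.amplitude_mm)
        assert len(got["twitch"]) > 100 and len(got["wake"]) > 100
        true_tw = np.mean([e.amplitude_mm for e in events if e.movement_class == "twitch"])
        true_wk = np.mean([e.amplitude_mm for e in events if e.movement_class == "wake"])
        assert np.mean(got["twitch"]) == pytest.approx(true_tw, rel=0.05)
        assert np.mean(got["wake"]) == pytest.approx(true_wk, rel=0.05)


class TestSpikeCount:
    def test_no_spikes_zero(self):
        spikes = SpikeTrain("n", np.array([]), (0.0, 10.0))
        ev = MovementEvent(5.0, "forelimb", "twitch")
        assert spike_count_in_activity_window(spikes, ev) == 0

    def test_boundary_arithmetic(self):
        spikes = SpikeTrain("n", np.array([9.929, 10.069]), (0.0, 20.0))
        ev = MovementEvent(10.0, "forelimb", "twitch")
        assert spike_count_in_activity_window(spikes, ev) == 1

    def test_conservation_against_bruteforce(self, rng):
        spikes = SpikeTrain("n", np.sort(rng.uniform(0, 100, 1500)), (0.0, 100.0))
        events = [MovementEvent(t, "forelimb", "wake")
                  for t in np.sort(rng.uniform(2, 98, 30))]
        total = sum(spike_count_in_activity_window(spikes, e, "wake") for e in events)
        brute = sum(
            int(np.sum((spikes.spike_times >= e.onset - 0.1)
                       & (spikes.spike_times < e.onset + 0.5)))
            for e in events
        )
        assert total == brute


def eta_squared_oracle(angles, counts, n_bins=12):
    """Independent eta^2 via a pandas group decomposition."""
    df = pd.DataFrame({
        "bin": np.floor((np.asarray(angles) % 360) / (360 / n_bins)).astype(int),
        "c": np.asarray(counts, dtype=float),
    })
    grand = df["c"].mean()
    ss_total = ((df["c"] - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = sum(
        len(g) * (g["c"].mean() - grand) ** 2 for _, g in df.groupby("bin")
    )
    return ss_between / ss_total


class TestEtaSquared:
    def test_constant_counts_zero(self):
        assert direction_eta_squared([10, 40, 200, 300], [5, 5, 5, 5]) == 0.0

    def test_fully_bin_determined_one(self):
        angles = [10, 15, 100, 105]
        counts = [2, 2, 9, 9]
        assert direction_eta_squared(angles, counts) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # bin A counts {3,5}, bin B counts {1,1}: SSB 9, SST 11
        angles = [10, 15, 100, 105]
        counts = [3, 5, 1, 1]
        assert direction_eta_squared(angles, counts) == pytest.approx(9 / 11)

    def test_fewer_than_two_bins_undefined(self):
        assert direction_eta_squared([10, 12, 14], [1, 2, 3]) is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        angles = rng.uniform(0, 360, n)
        counts = rng.poisson(4, n)
        if np.unique(np.floor(angles / 30).astype(int)).size < 2:
            return
        got = direction_eta_squared(angles, counts)
        assert got == pytest.approx(eta_squared_oracle(angles, counts), abs=1e-12)

    def test_order_invariance(self, rng):
        angles = rng.uniform(0, 360, 40)
        counts = rng.poisson(3, 40)
        perm = rng.permutation(40)
        assert direction_eta_squared(angles, counts) == pytest.approx(
            direction_eta_squared(angles[perm], counts[perm]), abs=1e-12)


class TestRSquared:
    def test_perfectly_linear_one(self):
        assert amplitude_r_squared([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_constant_counts_zero(self):
        assert amplitude_r_squared([1, 2, 3, 4], [5, 5, 5, 5]) == 0.0

    def test_hand_computed_pearson(self):
        # (1,1),(2,3),(3,2),(4,4): r = 0.8
        assert amplitude_r_squared([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.64)

    def test_zero_amplitude_variance_undefined(self):
        assert amplitude_r_squared([2, 2, 2, 2], [1, 3, 2, 4]) is None


class TestSelectivity:
    def test_example_neuron_both(self):
        t = TuningResult("n", eta_sq_direction=0.258, r_sq_amplitude=0.347, n_movements=454)
        assert classify_selectivity(t) == "both"

    def test_none(self):
        t = TuningResult("n", 0.05, 0.05, 100)
        assert classify_selectivity(t) == "none"

    def test_exactly_threshold_not_selective(self):
        t = TuningResult("n", 0.1, 0.1, 100)
        assert classify_selectivity(t) == "none"
        assert not t.direction_selective

    def test_undefined_undetermined(self):
        t = TuningResult("n", None, 0.3, 100)
        assert classify_selectivity(t) == "undetermined"


class TestPreferredSplit:
    def test_expected_four_prints_two_and_six(self):
        res = split_preferred_movements(np.array([0, 2, 3, 4, 5, 6, 9]), 4.0)
        assert res["non_preferred_threshold"] == 2
        assert res["preferred_threshold"] == 6
        assert list(res["non_preferred"]) == [0, 1]  # counts 0 and 2
        assert list(res["preferred"]) == [5, 6]  # counts 6 and 9

    def test_expected_ten(self):
        res = split_preferred_movements(np.array([5, 6, 14, 15]), 10.0)
        assert res["non_preferred_threshold"] == 5
        assert res["preferred_threshold"] == 15
        assert list(res["non_preferred"]) == [0]
        assert list(res["preferred"]) == [3]

    def test_all_middle_both_empty(self):
        res = split_preferred_movements(np.array([3, 4, 5]), 4.0)
        assert res["non_preferred"].size == 0 and res["preferred"].size == 0

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(InvalidParameterError):
            split_preferred_movements(np.array([1, 2]), 0.0)


@pytest.fixture(scope="module")
def wake_session():
    duration = 1400.0
    params = SimulationParams(
        session_duration=duration,
        state_mean_durations={"quiet_wake": duration},
        baseline_rate={"wake": 5.0}, wake_move_rate=0.35,
        angle_distribution={"mu_deg": 129.0, "kappa": 1.0},
        trajectory_noise_px=0.2, seed=37,
    )
    tl = simulate_state_timeline(params)
    events = simulate_movement_events(tl, params)
    traj = simulate_trajectory(events, params)
    return params, tl, events, traj


class TestTuningRecovery:
    def _tuning_for(self, wake_session, spec, child_seed):
        params, tl, events, traj = wake_session
        spikes = simulate_spike_train(events, tl, params, neuron=spec,
                                      rng=np.random.default_rng(child_seed))
        angles, amps, counts = [], [], []
        for ev in events:
            try:
                kin = compute_kinematics(traj, ev.onset, "wake")
            except InvalidParameterError:  # window past the trajectory end
                continue
            if kin.angle_deg is None:
                continue
            angles.append(kin.angle_deg)
            amps.append(kin.amplitude_mm)
            counts.append(spike_count_in_activity_window(spikes, ev, "wake"))
        return compute_tuning(spec.neuron_id, np.array(angles), np.array(amps),
                              np.array(counts))

    def test_tuned_neuron_exceeds_threshold(self, wake_session):
        _, _, events, _ = wake_session
        assert len(events) >= 400
        spec = NeuronSpec(
            "tuned", wake_kernel=ResponseKernel(100, 150, 12.0, 0.14),
            direction_tuning=DirectionTuning(mu_deg=129.0, kappa=3.0),
            amplitude_slope_per_mm=0.15,
        )
        t = self._tuning_for(wake_session, spec, 101)
        assert t.eta_sq_direction > 0.1
        assert t.r_sq_amplitude > 0.1
        assert classify_selectivity(t) == "both"

    def test_untuned_neuron_below_threshold(self, wake_session):
        for child in (301, 302, 303):
            spec = NeuronSpec("flat", wake_kernel=ResponseKernel(100, 150, 12.0, 0.14))
            t = self._tuning_for(wake_session, spec, child)
            assert t.eta_sq_direction < 0.1
            assert t.r_sq_amplitude < 0.1
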