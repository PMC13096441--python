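"""Synthetic session generator with known ground truth.

Simulates everything a recording session provides — a sleep/wake state
timeline, REM twitches and wake movements, inhomogeneous-Poisson spike
trains with movement-locked response kernels, a limb trajectory, ROI
pixel-change series, EMG/delta state features and an LED-synchronized frame
clock — so that every downstream stage of the package can be verified by
parameter recovery.

The movement-locked rate kernel is a skew-normal bump: its mode sits at the
requested response latency, its scale sets the response width, and its shape
parameter is solved numerically so that the fraction of kernel mass falling
before movement onset equals ``premove_fraction``. This gives a single
controllable ground truth for the premovement-proportion metric. Note the
geometry constrains feasibility: a kernel peaked ``latency`` after onset
with scale ``sigma`` can place at most ``2*Phi(-latency/sigma)`` of its mass
before onset (the left-half-normal limit); requesting more raises an error.

Baseline firing is state-dependent homogeneous Poisson; defaults follow
infant red-nucleus rates (13.1 spikes/s in REM vs 7.2 in wake). Movement
kinematics use von Mises angles (math convention: counterclockwise from +x,
0 deg = forward) and log-normal amplitudes whose class means default to
0.96 mm (twitches) and 6.95 mm (wake movements).

Determinism: the same :class:`SimulationParams` (including ``seed``) yields
bit-identical sessions; per-stage generators are spawned from one seed
sequence so stages remain independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import InvalidParameterError
from .types import (
    BODY_PARTS,
    FrameClock,
    MovementEvent,
    PixelChangeSeries,
    SpikeTrain,
    StateTimeline,
    Trajectory,
    sort_events,
)

_STATE_CYCLE = ("NREM", "REM", "quiet_wake")
_RATE_GRID_DT = 0.001  # s; rate discretization for spike generation


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class ResponseKernel:
    """Movement-locked firing-rate bump.

    gain is the kernel's total area in spikes per event; latency the mode of
    the bump relative to movement onset; sigma its scale; premove_fraction
    the kernel mass placed before onset.
    """

    latency_ms: float = 30.0
    sigma_ms: float = 45.0
    gain: float = 5.0
    premove_fraction: float = 0.29

    def __post_init__(self):
        if self.sigma_ms <= 0:
            raise InvalidParameterError("kernel sigma must be > 0")
        if self.gain < 0:
            raise InvalidParameterError("kernel gain must be >= 0")
        if not 0.0 <= self.premove_fraction <= 1.0:
            raise InvalidParameterError("premove_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DirectionTuning:
    """Von Mises gain profile over movement direction, peak 1 at mu."""

    mu_deg: float = 129.0
    kappa: float = 3.0


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth description of one simulated neuron."""

    neuron_id: str
    region: str = "M1"
    baseline_rate: dict | None = None  # spikes/s per state; None -> params default
    twitch_kernel: ResponseKernel | None = None
    wake_kernel: ResponseKernel | None = None
    responsive_body_parts: tuple[str, ...] = ("forelimb",)
    direction_tuning: DirectionTuning | None = None
    amplitude_slope_per_mm: float = 0.0


def _default_state_durations() -> dict:
    return {"NREM": 60.0, "REM": 45.0, "quiet_wake": 60.0}


def _default_baseline() -> dict:
    return {"REM": 13.1, "wake": 7.2, "NREM": 5.0}


def _default_amplitudes() -> dict:
    # log-normal parameters chosen so the class means are 0.96 mm (twitch)
    # and 6.95 mm (wake) with sigma_log 0.5: mean = exp(mu + sigma^2/2)
    s = 0.5
    return {
        "twitch": {"mu_log": math.log(0.96) - s * s / 2, "sigma_log": s},
        "wake": {"mu_log": math.log(6.95) - s * s / 2, "sigma_log": s},
    }


@dataclass(frozen=True)
class SimulationParams:
    session_duration: float = 1800.0  # s
    state_mean_durations: dict = field(default_factory=_default_state_durations)
    baseline_rate: dict = field(default_factory=_default_baseline)  # spikes/s
    response_kernel: ResponseKernel = field(default_factory=ResponseKernel)
    twitch_rate: float = 0.3  # events/s per body part during REM
    twitch_body_parts: tuple[str, ...] = ("forelimb", "hindlimb", "whiskers", "tail")
    wake_move_rate: float = 0.2  # candidate events/s during wake
    wake_quiescence_s: float = 0.5  # enforced minimum inter-onset spacing
    angle_distribution: dict = field(
        default_factory=lambda: {"mu_deg": 129.0, "kappa": 1.0}
    )
    amplitude_distribution: dict = field(default_factory=_default_amplitudes)
    frame_rate: float = 100.0  # frames/s
    pulse_interval: float = 3.0  # s
    dropped_frame_prob: float = 0.0
    trajectory_noise_px: float = 0.3
    pixel_noise_lambda: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.session_duration <= 0:
            raise InvalidParameterError("session_duration must be > 0")
        for state, dur in self.state_mean_durations.items():
            if dur <= 0:
                raise InvalidParameterError(f"mean duration for {state} must be > 0")
        for state, rate in self.baseline_rate.items():
            if rate < 0:
                raise InvalidParameterError(f"baseline rate for {state} must be >= 0")
        if self.twitch_rate < 0 or self.wake_move_rate < 0:
            raise InvalidParameterError("event rates must be >= 0")
        if not 0.0 <= self.dropped_frame_prob < 1.0:
            raise InvalidParameterError("dropped_frame_prob must be in [0, 1)")
        if self.frame_rate <= 0 or self.pulse_interval <= 0:
            raise InvalidParameterError("frame_rate and pulse_interval must be > 0")
        for part in self.twitch_body_parts:
            if part not in BODY_PARTS:
                raise InvalidParameterError(f"unknown body part {part!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    timeline: StateTimeline | None = None
    events: list[MovementEvent] = field(default_factory=list)
    dropped_frame_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    neuron_truth: dict = field(default_factory=dict)  # neuron_id -> dict
    pixel_pulses: dict = field(default_factory=dict)  # roi -> list[(f0, f1)]


# ---------------------------------------------------------------------------
# skew-normal kernel realization

def _skewnorm_mode_std(alpha: float) -> float:
    """Mode of the standard (loc 0, scale 1) skew normal, numerically."""
    if alpha == 0:
        return 0.0
    res = optimize.minimize_scalar(
        lambda x: -stats.skewnorm.pdf(x, alpha), bounds=(-4.0, 4.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def realize_kernel(kernel: ResponseKernel):
    """Frozen scipy distribution implementing a :class:`ResponseKernel`.

    Returns a frozen ``skewnorm`` over seconds relative to movement onset,
    with mode at ``latency_ms`` and ``cdf(0) == premove_fraction``.
    """
    latency = kernel.latency_ms / 1000.0
    sigma = kernel.sigma_ms / 1000.0
    target = kernel.premove_fraction

    def premass(alpha: float) -> float:
        loc = latency - sigma * _skewnorm_mode_std(alpha)
        return float(stats.skewnorm.cdf(0.0, alpha, loc=loc, scale=sigma))

    # premass is continuous but not monotone in alpha (pinning the mode
    # shifts loc), so bracket a sign change on a grid before root-finding
    grid = np.linspace(-40.0, 40.0, 81)
    masses = np.array([premass(a) for a in grid])
    diffs = masses - target
    crossing = np.flatnonzero(np.signbit(diffs[:-1]) != np.signbit(diffs[1:]))
    exact = np.flatnonzero(np.abs(diffs) < 1e-12)
    if exact.size:
        alpha = float(grid[exact[0]])
    elif crossing.size:
        i = int(crossing[0])
        alpha = optimize.brentq(
            lambda a: premass(a) - target, grid[i], grid[i + 1], xtol=1e-8
        )
    else:
        raise InvalidParameterError(
            f"premove_fraction {target} unreachable for latency {kernel.latency_ms} ms,"
            f" sigma {kernel.sigma_ms} ms (achievable range"
            f" [{masses.min():.4f}, {masses.max():.4f}]); increase sigma or adjust latency"
        )
    loc = latency - sigma * _skewnorm_mode_std(alpha)
    return stats.skewnorm(alpha, loc=loc, scale=sigma)


# ---------------------------------------------------------------------------
# state timeline

def simulate_state_timeline(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> StateTimeline:
    """Alternating NREM/REM/wake intervals with exponential dwell times.

    States cycle in the order NREM -> REM -> quiet wake, restricted to the
    states named in ``params.state_mean_durations``; the final interval is
    truncated so the intervals partition ``[0, session_duration]`` exactly.
    """
    if params.session_duration <= 0:  # re-checked for callers mutating params
        raise InvalidParameterError("session_duration must be > 0")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    cycle = [s for s in _STATE_CYCLE if s in params.state_mean_durations]
    if not cycle:
        raise InvalidParameterError("state_mean_durations names no simulated state")

    intervals: list[tuple[float, float, str]] = []
    t, i = 0.0, 0
    dur = params.session_duration
    while t < dur - 1e-12:
        state = cycle[i % len(cycle)]
        dwell = rng.exponential(params.state_mean_durations[state])
        end = min(t + dwell, dur)
        if end > t:
            if intervals and intervals[-1][2] == state:
                intervals[-1] = (intervals[-1][0], end, state)
            else:
                intervals.append((t, end, state))
        t = end
        i += 1
    return StateTimeline(intervals)


# ---------------------------------------------------------------------------
# movement events

def _poisson_times_in_intervals(
    intervals: list[tuple[float, float]], rate: float, rng: np.random.Generator
) -> np.ndarray:
    times: list[np.ndarray] = []
    for start, end in intervals:
        n = rng.poisson(rate * (end - start))
        if n:
            times.append(np.sort(rng.uniform(start, end, size=n)))
    if not times:
        return np.array([], dtype=float)
    return np.sort(np.concatenate(times))


def _draw_kinematics(
    n: int, movement_class: str, params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    ang = params.angle_distribution
    amp = params.amplitude_distribution[movement_class]
    mu = math.radians(ang["mu_deg"])
    if np.isinf(ang["kappa"]):
        angles = np.full(n, ang["mu_deg"])
    else:
        angles = np.degrees(rng.vonmises(mu, ang["kappa"], size=n)) % 360.0
    amplitudes = rng.lognormal(amp["mu_log"], amp["sigma_log"], size=n)
    return angles, amplitudes


def simulate_movement_events(
    timeline: StateTimeline,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list[MovementEvent]:
    """Twitches in REM (Poisson per body part) and spaced wake movements.

    Wake-movement onsets keep the generator's quiescence rule: candidate
    Poisson events closer than ``wake_quiescence_s`` to the previously kept
    onset are discarded, so returned wake onsets are pairwise >= 500 ms apart
    by default. NREM carries no events. Each event carries its true angle
    (von Mises) and amplitude (log-normal, per class) as ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    events: list[MovementEvent] = []

    rem = timeline.intervals_for("REM")
    for part in params.twitch_body_parts:
        onsets = _poisson_times_in_intervals(rem, params.twitch_rate, rng)
        angles, amps = _draw_kinematics(onsets.size, "twitch", params, rng)
        for t, a, amp in zip(onsets, angles, amps):
            events.append(
                MovementEvent(
                    onset=float(t), body_part=part, movement_class="twitch",
                    state="REM", amplitude_mm=float(amp), angle_deg=float(a),
                )
            )

    wake = timeline.intervals_for("wake")
    candidates = _poisson_times_in_intervals(wake, params.wake_move_rate, rng)
    kept: list[float] = []
    for t in candidates:
        if not kept or t - kept[-1] >= params.wake_quiescence_s:
            kept.append(float(t))
    angles, amps = _draw_kinematics(len(kept), "wake", params, rng)
    for t, a, amp in zip(kept, angles, amps):
        events.append(
            MovementEvent(
                onset=t, body_part="forelimb", movement_class="wake",
                state=timeline.state_at(t), amplitude_mm=float(amp),
                angle_deg=float(a),
            )
        )
    return sort_events(events)


# ---------------------------------------------------------------------------
# spike trains

def _event_gain(event: MovementEvent, kernel: ResponseKernel, neuron: NeuronSpec | None) -> float:
    g = kernel.gain
    if neuron is None or event.movement_class != "wake":
        return g
    if neuron.direction_tuning is not None and event.angle_deg is not None:
        tun = neuron.direction_tuning
        g *= math.exp(
            tun.kappa * (math.cos(math.radians(event.angle_deg - tun.mu_deg)) - 1.0)
        )
    if neuron.amplitude_slope_per_mm and event.amplitude_mm is not None:
        g *= max(0.0, 1.0 + neuron.amplitude_slope_per_mm * event.amplitude_mm)
    return g


def rate_on_grid(
    events: list[MovementEvent],
    timeline: StateTimeline,
    params: SimulationParams,
    neuron: NeuronSpec | None = None,
    dt: float = _RATE_GRID_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """The generator's own firing-rate function on a regular grid.

    Exposed so tests can use the exact intended rate as an oracle for
    event-triggered averages, independent of the spike draw.
    """
    t0, t1 = timeline.span
    n = int(round((t1 - t0) / dt))
    t = t0 + (np.arange(n) + 0.5) * dt
    base = neuron.baseline_rate if neuron is not None and neuron.baseline_rate else params.baseline_rate
    rate = np.zeros(n)
    for start, end, state in timeline.intervals:
        r = base.get(state)
        if r is None and state.endswith("wake"):
            r = base.get("wake")
        if r is None:
            r = 0.0
        if r < 0:
            raise InvalidParameterError(f"negative baseline rate for state {state}")
        rate[(t >= start) & (t < end)] = r

    kernels: dict[str, object] = {}

    def kernel_for(event: MovementEvent) -> ResponseKernel | None:
        if neuron is None:
            return params.response_kernel
        if event.body_part not in neuron.responsive_body_parts:
            return None
        return neuron.twitch_kernel if event.movement_class == "twitch" else neuron.wake_kernel

    for ev in events:
        spec = kernel_for(ev)
        if spec is None or spec.gain == 0:
            continue
        key = (spec.latency_ms, spec.sigma_ms, spec.premove_fraction)
        if key not in kernels:
            kernels[key] = realize_kernel(spec)
        dist = kernels[key]
        gain = _event_gain(ev, spec, neuron)
        half = 8.0 * spec.sigma_ms / 1000.0
        lo = max(t0, ev.onset - half)
        hi = min(t1, ev.onset + half + spec.latency_ms / 1000.0)
        i0, i1 = int((lo - t0) / dt), int(np.ceil((hi - t0) / dt))
        seg = t[i0:i1] - ev.onset
        rate[i0:i1] += gain * dist.pdf(seg)
    return t, np.maximum(rate, 0.0)


def simulate_spike_train(
    events: list[MovementEvent],
    timeline: StateTimeline,
    params: SimulationParams,
    neuron: NeuronSpec | None = None,
    rng: np.random.Generator | None = None,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes: state baseline + movement kernels.

    The rate is piecewise constant on a 1 ms grid; per-bin Poisson counts
    with uniform within-bin jitter realize an (exactly) inhomogeneous
    Poisson process for that discretized rate.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    t, rate = rate_on_grid(events, timeline, params, neuron=neuron)
    dt = _RATE_GRID_DT
    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(counts.size), counts)
    times = t[idx] - dt / 2 + rng.uniform(0.0, dt, size=idx.size)
    times.sort()
    t0, t1 = timeline.span
    times = times[(times >= t0) & (times < t1)]
    return SpikeTrain(
        neuron_id=neuron.neuron_id if neuron is not None else "sim",
        spike_times=times,
        session_span=(t0, t1),
        region_label=neuron.region if neuron is not None else "",
    )


# ---------------------------------------------------------------------------
# trajectory, pixel-change, frame clock, state features

def _excursion_profile(n: int) -> np.ndarray:
    # triangular: exactly 0 at the onset frame, exactly 1 at the mid-window
    # peak frame, back to 0 — so the drawn amplitude is realized on-grid
    m = max(1, n // 2)
    return np.maximum(0.0, 1.0 - np.abs(np.arange(n) - m) / m)


def simulate_trajectory(
    events: list[MovementEvent],
    params: SimulationParams,
    duration: float | None = None,
    calibration: float = 5.75,
    bodypart: str = "forelimb",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Per-frame limb position in image coordinates.

    Each event for ``bodypart`` produces a triangular excursion whose peak
    displacement is the event's ground-truth amplitude (mm, converted at
    ``calibration`` px/mm) along its ground-truth angle. Math-convention
    angles are mapped to image coordinates by flipping y (y grows downward
    in images). Twitch excursions last 150 ms, wake excursions 500 ms.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 3)
    if duration is None:
        duration = params.session_duration
    n = int(round(duration * params.frame_rate))
    times = np.arange(n) / params.frame_rate
    x = np.full(n, 360.0) + rng.normal(0.0, params.trajectory_noise_px, n)
    y = np.full(n, 270.0) + rng.normal(0.0, params.trajectory_noise_px, n)
    for ev in events:
        if ev.body_part != bodypart or ev.amplitude_mm is None or ev.angle_deg is None:
            continue
        window = 0.150 if ev.movement_class == "twitch" else 0.500
        i0 = int(round(ev.onset * params.frame_rate))
        n_frames = int(round(window * params.frame_rate))
        i1 = min(n, i0 + n_frames)
        if i0 >= n:
            continue
        prof = _excursion_profile(n_frames)[: i1 - i0]
        a_px = ev.amplitude_mm * calibration
        theta = math.radians(ev.angle_deg)
        x[i0:i1] += a_px * math.cos(theta) * prof
        y[i0:i1] -= a_px * math.sin(theta) * prof  # image y is flipped
    likelihood = rng.uniform(0.9, 1.0, n)
    return Trajectory(
        bodypart=bodypart, times=times, x=x, y=y,
        likelihood=likelihood, calibration=calibration,
    )


def simulate_pixel_change_series(
    events: list[MovementEvent],
    params: SimulationParams,
    duration: float | None = None,
    roi_label: str = "whole_body",
    pulse_height: int = 150,
    rng: np.random.Generator | None = None,
    ground_truth: GroundTruth | None = None,
) -> PixelChangeSeries:
    """100 Hz count series of changed pixels with an elevated pulse per event.

    Baseline frames carry Poisson noise counts; an event adds a decaying
    pulse starting at its onset frame (5 frames for twitches, 40 for wake
    movements). Pulse extents — including merges of overlapping pulses —
    are recorded in ``ground_truth.pixel_pulses`` when provided.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 4)
    if duration is None:
        duration = params.session_duration
    n = int(round(duration * params.frame_rate))
    values = rng.poisson(params.pixel_noise_lambda, n)
    spans: list[tuple[int, int]] = []
    for ev in events:
        i0 = int(round(ev.onset * params.frame_rate))
        n_frames = 5 if ev.movement_class == "twitch" else 40
        i1 = min(n, i0 + n_frames)
        if i0 >= n:
            continue
        pulse = np.linspace(pulse_height, pulse_height // 4, i1 - i0).astype(int)
        values[i0:i1] += pulse
        if spans and i0 <= spans[-1][1]:  # merged with the previous pulse
            spans[-1] = (spans[-1][0], max(spans[-1][1], i1))
        else:
            spans.append((i0, i1))
    if ground_truth is not None:
        ground_truth.pixel_pulses[roi_label] = spans
    return PixelChangeSeries(values=values, frame_rate=params.frame_rate, roi_label=roi_label)


def simulate_frame_clock(
    params: SimulationParams,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    ground_truth: GroundTruth | None = None,
) -> FrameClock:
    """Frame timestamps with independent drops plus LED pulse times.

    Each nominal frame (at ``frame_rate``) is deleted independently with
    probability ``dropped_frame_prob``; dropped indices go to ground truth.
    """
    if not 0.0 <= params.dropped_frame_prob < 1.0:
        raise InvalidParameterError("dropped_frame_prob must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(params.seed + 5)
    if duration is None:
        duration = params.session_duration
    n = int(round(duration * params.frame_rate))
    ideal = np.arange(n) / params.frame_rate
    dropped = rng.random(n) < params.dropped_frame_prob
    dropped[0] = False  # the first frame anchors the clock
    pulses = np.arange(0.0, duration, params.pulse_interval)
    if ground_truth is not None:
        ground_truth.dropped_frame_indices = np.flatnonzero(dropped)
    return FrameClock(
        frame_times=ideal[~dropped],
        pulse_times=pulses,
        frame_rate=params.frame_rate,
        pulse_interval=params.pulse_interval,
    )


def simulate_state_features(
    timeline: StateTimeline,
    dt: float = 0.1,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nuchal-tone and cortical-delta traces consistent with a timeline.

    Tone is high in wake, moderate in NREM and near zero (atonia) in REM;
    delta power is high in NREM only. Returns (times, tone, delta).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    t0, t1 = timeline.span
    t = np.arange(t0, t1, dt)
    tone_level = {"REM": 0.05, "NREM": 0.5, "quiet_wake": 1.0, "active_wake": 1.1}
    delta_level = {"REM": 0.2, "NREM": 1.0, "quiet_wake": 0.2, "active_wake": 0.2}
    tone = np.zeros(t.size)
    delta = np.zeros(t.size)
    for start, end, state in timeline.intervals:
        m = (t >= start) & (t < end)
        tone[m] = tone_level[state]
        delta[m] = delta_level[state]
    tone = np.clip(tone + rng.normal(0, noise_sd, t.size), 0, None)
    delta = np.clip(delta + rng.normal(0, noise_sd, t.size), 0, None)
    return t, tone, delta


# ---------------------------------------------------------------------------
# whole sessions

@dataclass
class SessionData:
    """A complete simulated session plus its ground truth."""

    params: SimulationParams
    timeline: StateTimeline
    events: list[MovementEvent]
    spike_trains: list[SpikeTrain]
    trajectory: Trajectory
    pixel_series: dict  # roi label -> PixelChangeSeries
    frame_clock: FrameClock
    state_features: tuple  # (times, tone, delta)
    ground_truth: GroundTruth


def default_neurons() -> list[NeuronSpec]:
    """Four-neuron roster: forelimb-tuned, untuned, kinematically tuned, wake-only."""
    twitch_k = ResponseKernel(latency_ms=30, sigma_ms=45, gain=5.0, premove_fraction=0.29)
    wake_k = ResponseKernel(latency_ms=100, sigma_ms=150, gain=10.0, premove_fraction=0.07)
    return [
        NeuronSpec("forelimb_tuned", region="M1", twitch_kernel=twitch_k, wake_kernel=wake_k),
        NeuronSpec("untuned", region="M1", twitch_kernel=None, wake_kernel=None),
        NeuronSpec(
            "kinematic_tuned", region="RN",
            twitch_kernel=ResponseKernel(15, 45, 5.0, 0.45),
            wake_kernel=ResponseKernel(100, 150, 12.0, 0.14),
            direction_tuning=DirectionTuning(mu_deg=129.0, kappa=3.0),
            amplitude_slope_per_mm=0.15,
        ),
        NeuronSpec("wake_only", region="M1", twitch_kernel=None, wake_kernel=wake_k),
    ]


def simulate_session(
    params: SimulationParams, neurons: list[NeuronSpec] | None = None
) -> SessionData:
    """Generate a full session; same params (incl. seed) => identical output."""
    if neurons is None:
        neurons = default_neurons()
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(6 + len(neurons))
    rng_tl, rng_ev, rng_traj, rng_px, rng_clock, rng_feat = (
        np.random.default_rng(c) for c in children[:6]
    )
    gt = GroundTruth()
    timeline = simulate_state_timeline(params, rng=rng_tl)
    events = simulate_movement_events(timeline, params, rng=rng_ev)
    gt.timeline = timeline
    gt.events = events

    trains = []
    for spec, child in zip(neurons, children[6:]):
        rng_n = np.random.default_rng(child)
        trains.append(simulate_spike_train(events, timeline, params, neuron=spec, rng=rng_n))
        truth = {
            "region": spec.region,
            "responsive_body_parts": list(spec.responsive_body_parts),
            "direction_tuned": spec.direction_tuning is not None,
            "amplitude_tuned": spec.amplitude_slope_per_mm != 0.0,
        }
        for label, k in (("twitch", spec.twitch_kernel), ("wake", spec.wake_kernel)):
            if k is not None:
                truth[f"{label}_latency_ms"] = k.latency_ms
                truth[f"{label}_sigma_ms"] = k.sigma_ms
                truth[f"{label}_premove_fraction"] = k.premove_fraction
        gt.neuron_truth[spec.neuron_id] = truth

    trajectory = simulate_trajectory(events, params, rng=rng_traj)
    pixel_series = {}
    for part in params.twitch_body_parts:
        part_events = [e for e in events if e.body_part == part and e.movement_class == "twitch"]
        pixel_series[part] = simulate_pixel_change_series(
            part_events, params, roi_label=part, rng=np.random.default_rng(rng_px.integers(2**31)),
            ground_truth=gt,
        )
    wake_events = [e for e in events if e.movement_class == "wake"]
    pixel_series["whole_body"] = simulate_pixel_change_series(
        wake_events, params, roi_label="whole_body",
        rng=np.random.default_rng(rng_px.integers(2**31)), ground_truth=gt,
    )
    clock = simulate_frame_clock(params, rng=rng_clock, ground_truth=gt)
    features = simulate_state_features(timeline, rng=rng_feat)
    return SessionData(
        params=params, timeline=timeline, events=events, spike_trains=trains,
        trajectory=trajectory, pixel_series=pixel_series, frame_clock=clock,
        state_features=features, ground_truth=gt,
    )
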