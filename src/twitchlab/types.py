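"""Core domain containers.

Conventions used package-wide: times are float seconds from session start,
frame indices are 0-based, and all intervals/bins are half-open
``[start, end)``. Behavioral states are ``NREM``, ``REM``, ``quiet_wake``
and ``active_wake``; a plain ``wake`` key in rate maps applies to both wake
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

STATES = ("NREM", "REM", "quiet_wake", "active_wake")
BODY_PARTS = ("forelimb", "hindlimb", "whiskers", "tail", "whole_body")
MOVEMENT_CLASSES = ("twitch", "wake")


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise InvalidParameterError("expected a 1-D array of times")
    if np.any(np.isnan(a)):
        raise InvalidParameterError("times must not contain NaN")
    return a


@dataclass(frozen=True)
class SpikeTrain:
    """One neuron's sorted spike times over a recording session."""

    neuron_id: str
    spike_times: np.ndarray  # seconds, ascending
    session_span: tuple[float, float]
    region_label: str = ""

    def __post_init__(self):
        times = _as_float_array(self.spike_times)
        if np.any(np.diff(times) < 0):
            times = np.sort(times)
        object.__setattr__(self, "spike_times", times)
        t0, t1 = self.session_span
        if not t1 > t0:
            raise InvalidParameterError("session_span must satisfy t0 < t1")
        if times.size and (times[0] < t0 or times[-1] >= t1):
            raise InvalidParameterError(
                f"spike times of {self.neuron_id} fall outside session span [{t0}, {t1})"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.session_span[1] - self.session_span[0]

    def mean_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass
class MovementEvent:
    """A scored movement onset."""

    onset: float  # s
    body_part: str
    movement_class: str  # "twitch" | "wake"
    state: str | None = None
    peak_displacement: float | None = None  # normalized ROI units
    amplitude_mm: float | None = None
    angle_deg: float | None = None
    offset: float | None = None  # bout end, s (when detected from ROI series)

    def __post_init__(self):
        if self.movement_class not in MOVEMENT_CLASSES:
            raise InvalidParameterError(
                f"movement class {self.movement_class!r} not in {MOVEMENT_CLASSES}"
            )
        if self.body_part not in BODY_PARTS:
            raise InvalidParameterError(
                f"body part {self.body_part!r} not in {BODY_PARTS}"
            )


def event_onsets(events: list[MovementEvent]) -> np.ndarray:
    return np.array([e.onset for e in events], dtype=float)


def sort_events(events: list[MovementEvent]) -> list[MovementEvent]:
    return sorted(events, key=lambda e: e.onset)


@dataclass
class StateTimeline:
    """Non-overlapping labeled intervals covering the session span exactly.

    ``intervals`` is a list of ``(start, end, state)`` with half-open
    ``[start, end)`` semantics.
    """

    intervals: list[tuple[float, float, str]]

    def __post_init__(self):
        if not self.intervals:
            raise InvalidParameterError("timeline must contain at least one interval")
        prev_end = None
        for start, end, state in self.intervals:
            if state not in STATES:
                raise InvalidParameterError(f"unknown state {state!r}")
            if not end > start:
                raise InvalidParameterError(
                    f"interval ({start}, {end}) must have start < end"
                )
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise InvalidParameterError(
                    f"timeline has a gap/overlap at t={prev_end} -> {start}"
                )
            prev_end = end

    @property
    def span(self) -> tuple[float, float]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def duration_by_state(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for start, end, state in self.intervals:
            out[state] = out.get(state, 0.0) + (end - start)
        return out

    def state_at(self, t: float) -> str | None:
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        return None

    def intervals_for(self, state: str) -> list[tuple[float, float]]:
        if state == "wake":
            keep = ("quiet_wake", "active_wake")
        else:
            keep = (state,)
        return [(s, e) for s, e, st in self.intervals if st in keep]


@dataclass
class Trajectory:
    """Markerless-tracking trajectory of one body part.

    Coordinates are image pixels (y increases downward); ``calibration`` is
    pixels per millimetre.
    """

    bodypart: str
    times: np.ndarray  # s, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px
    likelihood: np.ndarray  # 0-1
    calibration: float  # px / mm

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = self.times.size
        if not (self.x.size == self.y.size == self.likelihood.size == n):
            raise InvalidParameterError("trajectory columns must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("frame times must be strictly increasing")
        if self.calibration <= 0:
            raise InvalidParameterError("calibration must be > 0 px/mm")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass
class FrameClock:
    """Video frame timestamps plus the LED sync-pulse record."""

    frame_times: np.ndarray  # s, strictly increasing
    pulse_times: np.ndarray  # s, strictly increasing
    frame_rate: float  # nominal frames/s
    pulse_interval: float  # s
    dummy_flags: np.ndarray | None = None  # bool per frame

    def __post_init__(self):
        self.frame_times = _as_float_array(self.frame_times)
        self.pulse_times = _as_float_array(self.pulse_times)
        if np.any(np.diff(self.frame_times) <= 0):
            raise InvalidParameterError("frame times must be strictly increasing")
        if self.pulse_interval <= 0 or self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate and pulse_interval must be > 0")
        if self.dummy_flags is None:
            self.dummy_flags = np.zeros(self.frame_times.size, dtype=bool)
        else:
            self.dummy_flags = np.asarray(self.dummy_flags, dtype=bool)
            if self.dummy_flags.size != self.frame_times.size:
                raise InvalidParameterError("dummy_flags length must match frames")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def real_frame_times(self) -> np.ndarray:
        """Timestamps of captured (non-dummy) frames."""
        return self.frame_times[~self.dummy_flags]


@dataclass
class PixelChangeSeries:
    """Per-frame count of pixels whose intensity changed by more than 5%."""

    values: np.ndarray  # non-negative ints, one per frame
    frame_rate: float = 100.0
    roi_label: str = "whole_body"
    roi_size: int | None = None
    start_time: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.size and (np.any(v < 0) or not np.issubdtype(v.dtype, np.integer)):
            if np.any(v < 0) or np.any(v != np.round(v)):
                raise InvalidParameterError("pixel-change values must be non-negative integers")
            v = v.astype(int)
        self.values = v.astype(int)
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be > 0")

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.frame_rate


@dataclass
class Peth:
    """Event-aligned spike-count matrix with baseline statistics.

    ``counts[i, j]`` holds spikes of event i in bin ``[edges[j], edges[j+1])``
    relative to that event's onset. ``mean_trace`` is the per-bin mean across
    events, in spikes/bin. The z-scored trace and baseline statistics are
    filled in by :func:`twitchlab.peth.zscore_peth`.
    """

    counts: np.ndarray  # (n_events, n_bins) int
    bin_edges: np.ndarray  # (n_bins + 1,) s relative to onset
    n_events: int
    baseline_window: tuple[float, float] = (-3.0, -0.5)
    baseline_mean: float | None = None  # spikes/bin
    baseline_sd: float | None = None  # spikes/bin
    z_trace: np.ndarray | None = None  # per bin

    @property
    def n_bins(self) -> int:
        return int(self.bin_edges.size - 1)

    @property
    def bin_size(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_trace(self) -> np.ndarray:
        """Mean spikes per bin across events."""
        return self.counts.mean(axis=0)

    def baseline_bin_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window
        c = self.bin_centers
        return (c >= lo) & (c < hi)


@dataclass
class NeuronClassification:
    """Movement-activity classification of one neuron."""

    neuron_id: str
    twitch_active: bool = False
    wake_active: bool = False
    twitch_status: str = "not_evaluated"
    wake_status: str = "not_evaluated"
    preferred_body_part: str | None = None
    peak_z_by_body_part: dict[str, float] = field(default_factory=dict)
    n_events_by_body_part: dict[str, int] = field(default_factory=dict)


@dataclass
class MovementKinematics:
    """Per-movement amplitude/angle derived from a limb trajectory."""

    amplitude_mm: float
    angle_deg: float | None  # None when amplitude == 0
    onset_position_px: tuple[float, float]
    peak_time: float  # s, absolute
    window_s: float


@dataclass
class TuningResult:
    """Per-neuron kinematic selectivity."""

    neuron_id: str
    eta_sq_direction: float | None
    r_sq_amplitude: float | None
    n_movements: int
    threshold: float = 0.1

    @property
    def direction_selective(self) -> bool:
        return self.eta_sq_direction is not None and self.eta_sq_direction > self.threshold

    @property
    def amplitude_selective(self) -> bool:
        return self.r_sq_amplitude is not None and self.r_sq_amplitude > self.threshold
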