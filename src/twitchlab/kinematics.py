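"""Movement kinematics and neuronal direction/amplitude selectivity.

Each movement's kinematics come from the limb trajectory: the initiation
location is the limb position at the onset frame; amplitude is the peak
Euclidean displacement from that origin within the kinematic window
(150 ms for twitches, 500 ms for wake movements), converted px -> mm at the
camera calibration (5.75 px/mm); the angle is the direction of the
onset -> peak vector in math convention (counterclockwise from +x, 0 deg =
forward), with the image y-axis flipped.

Selectivity statistics relate per-movement spike counts (in the activity
window: -70..70 ms twitches, -100..500 ms wake) to kinematics: eta^2 is
the one-way between-bin variance fraction over 12 equal 30-degree
direction bins; r^2 is the squared Pearson correlation between count and
amplitude. Neurons exceeding 0.1 (strictly) are selective.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .errors import InsufficientDataError, InvalidParameterError
from .types import MovementEvent, MovementKinematics, Trajectory, TuningResult

logger = logging.getLogger(__name__)


def compute_kinematics(
    traj: Trajectory,
    onset: float,
    movement_class: str = "twitch",
    config: AnalysisConfig | None = None,
) -> MovementKinematics:
    """Amplitude (mm) and angle (deg) of one movement from a trajectory.

    The angle convention is mathematical (counterclockwise from +x, y up);
    image coordinates are converted by negating dy. With ``angle_mode``
    "path_mean" the angle is instead the circular mean of the per-frame
    onset->position vectors up to the peak.
    """
    config = config or AnalysisConfig()
    window = (config.kinematic_window_twitch_s if movement_class == "twitch"
              else config.kinematic_window_wake_s)
    i0 = int(np.searchsorted(traj.times, onset, side="right")) - 1
    if i0 < 0:
        raise InvalidParameterError(f"onset {onset} s precedes the trajectory")
    i1 = int(np.searchsorted(traj.times, onset + window, side="right"))
    dt = float(np.median(np.diff(traj.times))) if traj.n_frames > 1 else 0.0
    if i1 - i0 < 2 or traj.times[i1 - 1] < onset + window - 2 * dt - 1e-9:
        raise InvalidParameterError(
            f"trajectory does not cover [{onset:.3f}, {onset + window:.3f}] s;"
            " kinematics undefined for this movement"
        )
    x0, y0 = float(traj.x[i0]), float(traj.y[i0])
    dx = traj.x[i0:i1] - x0
    dy = -(traj.y[i0:i1] - y0)  # flip image y to math convention
    disp = np.hypot(dx, dy)
    i_peak = int(np.argmax(disp))
    amplitude_px = float(disp[i_peak])
    amplitude_mm = amplitude_px / traj.calibration

    if amplitude_px == 0:
        angle = None
    elif config.angle_mode == "path_mean":
        m = disp[: i_peak + 1] > 0
        if not m.any():
            angle = None
        else:
            angles = np.arctan2(dy[: i_peak + 1][m], dx[: i_peak + 1][m])
            angle = math.degrees(
                math.atan2(np.sin(angles).mean(), np.cos(angles).mean())
            ) % 360.0
    else:
        angle = math.degrees(math.atan2(dy[i_peak], dx[i_peak])) % 360.0
    return MovementKinematics(
        amplitude_mm=amplitude_mm, angle_deg=angle,
        onset_position_px=(x0, y0),
        peak_time=float(traj.times[i0 + i_peak]), window_s=window,
    )


def spike_count_in_activity_window(
    spikes, event: MovementEvent, movement_class: str | None = None,
    config: AnalysisConfig | None = None,
) -> int:
    """Spikes in the half-open activity window around one movement onset."""
    config = config or AnalysisConfig()
    cls = movement_class or event.movement_class
    w = (config.activity_window_twitch_s if cls == "twitch"
         else config.activity_window_wake_s)
    lo = np.searchsorted(spikes.spike_times, event.onset + w[0], side="left")
    hi = np.searchsorted(spikes.spike_times, event.onset + w[1], side="left")
    return int(hi - lo)


def direction_eta_squared(
    angles_deg: np.ndarray,
    counts: np.ndarray,
    n_bins: int = 12,
) -> float | None:
    """One-way effect size of direction bin on spike count.

    Movements are grouped into ``n_bins`` equal directional bins
    ([0, 30), [30, 60), ... at defaults); eta^2 = SS_between / SS_total
    with grand-mean decomposition and empty bins dropped. All-equal counts
    give 0; fewer than two non-empty bins leave the statistic undefined.
    """
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    counts = np.asarray(counts, dtype=float)
    if angles.size != counts.size:
        raise InvalidParameterError("angles and counts must have equal length")
    bins = np.floor(angles / (360.0 / n_bins)).astype(int) % n_bins
    occupied = np.unique(bins)
    if occupied.size < 2:
        logger.warning("fewer than 2 non-empty direction bins; eta^2 undefined")
        return None
    grand = counts.mean()
    ss_total = float(np.sum((counts - grand) ** 2))
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for b in occupied:
        group = counts[bins == b]
        ss_between += group.size * (group.mean() - grand) ** 2
    return float(ss_between / ss_total)


def amplitude_r_squared(
    amplitudes_mm: np.ndarray, counts: np.ndarray
) -> float | None:
    """Squared Pearson correlation between movement amplitude and count.

    Identical to simple-linear-regression R^2 with intercept. Zero count
    variance gives 0; zero amplitude variance leaves it undefined.
    """
    a = np.asarray(amplitudes_mm, dtype=float)
    c = np.asarray(counts, dtype=float)
    if a.size != c.size:
        raise InvalidParameterError("amplitudes and counts must have equal length")
    if a.size < 3:
        raise InsufficientDataError("amplitude r^2 needs at least 3 movements")
    if np.var(a) == 0:
        logger.warning("zero amplitude variance; r^2 undefined")
        return None
    if np.var(c) == 0:
        return 0.0
    r, _ = sps.pearsonr(a, c)
    return float(r * r)


def compute_tuning(
    neuron_id: str,
    angles_deg: np.ndarray,
    amplitudes_mm: np.ndarray,
    counts: np.ndarray,
    config: AnalysisConfig | None = None,
) -> TuningResult:
    config = config or AnalysisConfig()
    return TuningResult(
        neuron_id=neuron_id,
        eta_sq_direction=direction_eta_squared(angles_deg, counts, config.n_direction_bins),
        r_sq_amplitude=amplitude_r_squared(amplitudes_mm, counts),
        n_movements=int(np.asarray(counts).size),
        threshold=config.selectivity_threshold,
    )


def classify_selectivity(t: TuningResult) -> str:
    """Selectivity class via strict > threshold comparisons.

    Returns one of ``none``, ``amplitude_only``, ``direction_only``,
    ``both``; an undefined statistic makes the class ``undetermined``.
    """
    if t.eta_sq_direction is None or t.r_sq_amplitude is None:
        return "undetermined"
    d = t.eta_sq_direction > t.threshold
    a = t.r_sq_amplitude > t.threshold
    if d and a:
        return "both"
    if d:
        return "direction_only"
    if a:
        return "amplitude_only"
    return "none"


def split_preferred_movements(
    counts: np.ndarray, expected_count: float
) -> dict:
    """Split movements into preferred / non-preferred by evoked spikes.

    Relative to the count expected from baseline firing alone in the
    post-onset window, movements with at least 50% fewer spikes
    (count <= 0.5 x expected, inclusive) are non-preferred and movements
    with at least 50% more (count >= 1.5 x expected, inclusive) are
    preferred; the rest stay unassigned. Integer thresholds are reported as
    the largest/smallest integers satisfying each rule (expected 4 ->
    "2 or fewer" / "6 or more").
    """
    if expected_count <= 0:
        raise InvalidParameterError("expected_count must be > 0 for a preferred split")
    counts = np.asarray(counts)
    lo, hi = 0.5 * expected_count, 1.5 * expected_count
    non_pref = np.flatnonzero(counts <= lo)
    pref = np.flatnonzero(counts >= hi)
    middle = np.flatnonzero((counts > lo) & (counts < hi))
    return {
        "non_preferred": non_pref,
        "preferred": pref,
        "middle": middle,
        "non_preferred_threshold": int(math.floor(lo)),
        "preferred_threshold": int(math.ceil(hi)),
    }
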