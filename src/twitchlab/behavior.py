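"""Movement detection, twitch isolation, state scoring and EMG rules.

Candidate movements come from ROI pixel-change series: for each region of
interest, the count of pixels whose intensity changed by more than 5% forms
a 100 Hz series, and a candidate movement starts at the first frame in
which the series exceeds threshold. Wake-movement onsets additionally
require at least 500 ms of behavioral quiescence since the previous
movement; twitch somatotopy analyses use only twitches isolated by at least
100 ms from twitches of other (or the same) body parts.

Behavioral state is scored with a simplified rule-based classifier: REM is
nuchal atonia with twitching, NREM is high cortical delta power with
quiescence, everything else is wake; wake within 3 s after a movement is
active wake. Thresholds default to quantiles of each trace (tone < 20th
percentile = atonia, delta > 70th percentile = high) since expert visual
scoring has no numeric rule.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .errors import AlignmentError, EmptyResultError, InvalidParameterError
from .types import MovementEvent, PixelChangeSeries, StateTimeline, sort_events

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LFP preprocessing

def preprocess_lfp(raw: np.ndarray, fs: float, target_fs: float = 1000.0) -> np.ndarray:
    """Gaussian-smooth (half-width 0.5 ms) then decimate to ~1000 Hz.

    The decimation factor is ``round(fs / target_fs)``; the output is
    truncated to ``floor(n * target_fs / fs)`` samples.
    """
    if fs < target_fs:
        raise InvalidParameterError(f"sampling rate {fs} Hz is below {target_fs} Hz")
    raw = np.asarray(raw, dtype=float)
    sigma_samples = 0.5e-3 * fs  # 0.5 ms half-width
    smoothed = ndimage.gaussian_filter1d(raw, sigma_samples, mode="nearest")
    factor = max(1, int(round(fs / target_fs)))
    out = smoothed[::factor]
    n_out = int(np.floor(raw.size * target_fs / fs))
    return out[:n_out]


# ---------------------------------------------------------------------------
# ROI-based movement detection

def roi_threshold(series: PixelChangeSeries, mad_factor: float = 3.0) -> float:
    """Default candidate threshold: median + mad_factor x scaled MAD."""
    v = series.values.astype(float)
    med = np.median(v)
    mad = 1.4826 * np.median(np.abs(v - med))
    return float(med + mad_factor * max(mad, 1.0))


def detect_movement_bouts(
    series: PixelChangeSeries,
    onset_threshold: float | None = None,
    body_part: str | None = None,
    movement_class: str = "twitch",
    config: AnalysisConfig | None = None,
) -> list[MovementEvent]:
    """Candidate movements at upward threshold crossings.

    Onset is the time of the first frame strictly above threshold; the bout
    ends when the series falls back below threshold. When no threshold is
    given the MAD-based default from :func:`roi_threshold` is used and
    logged. Bouts shorter than ``config.roi_min_bout_frames`` frames are
    discarded as sensor noise (the automated stand-in for manual video
    confirmation of each candidate).
    """
    config = config or AnalysisConfig()
    if onset_threshold is None:
        onset_threshold = roi_threshold(series, config.roi_threshold_mad_factor)
        logger.info("ROI %s: automatic threshold %.2f counts", series.roi_label, onset_threshold)
    if onset_threshold <= 0:
        raise InvalidParameterError("onset threshold must be > 0")
    above = series.values > onset_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    times = series.times()
    part = body_part or series.roi_label
    if part not in ("forelimb", "hindlimb", "whiskers", "tail", "whole_body"):
        part = "whole_body"
    dt = 1.0 / series.frame_rate
    return [
        MovementEvent(
            onset=float(times[s]), body_part=part, movement_class=movement_class,
            peak_displacement=float(series.values[s:e].max()),
            offset=float(times[e - 1] + dt),
        )
        for s, e in zip(starts, ends)
        if e - s >= config.roi_min_bout_frames
    ]


def mark_wake_movement_onsets(
    candidates: list[MovementEvent],
    quiescence_gap: float = 0.5,
) -> list[MovementEvent]:
    """Keep only onsets preceded by >= ``quiescence_gap`` of quiescence.

    Greedy from the left: the first candidate of a bout is kept; a later
    candidate is kept only if at least the gap separates its onset from the
    end of the preceding candidate (any candidate, kept or not). The
    comparison is inclusive ("at least 500 ms").
    """
    out: list[MovementEvent] = []
    prev_end: float | None = None
    for ev in sort_events(candidates):
        if prev_end is None or ev.onset - prev_end >= quiescence_gap:
            out.append(MovementEvent(
                onset=ev.onset, body_part=ev.body_part, movement_class="wake",
                state=ev.state, peak_displacement=ev.peak_displacement,
                offset=ev.offset,
            ))
        prev_end = ev.offset if ev.offset is not None else ev.onset
    return out


def isolate_twitches(
    events: list[MovementEvent],
    window: float = 0.1,
    mode: str = "cross_bodypart",
) -> list[MovementEvent]:
    """Twitches separated from neighboring twitches by at least ``window``.

    ``cross_bodypart`` keeps twitches with no other-body-part twitch within
    +/- window (the somatotopy rule); ``same_bodypart`` additionally requires
    >= window to the nearest same-body-part twitch (the displacement-profile
    rule). Non-twitch events are ignored; output is a subset of the input.
    """
    if mode not in ("cross_bodypart", "same_bodypart"):
        raise InvalidParameterError(f"unknown isolation mode {mode!r}")
    twitches = [e for e in sort_events(events) if e.movement_class == "twitch"]
    out = []
    for i, ev in enumerate(twitches):
        ok = True
        for j, other in enumerate(twitches):
            if j == i:
                continue
            gap = abs(other.onset - ev.onset)
            if gap >= window:
                continue
            if other.body_part != ev.body_part or mode == "same_bodypart":
                ok = False
                break
        if ok:
            out.append(ev)
    return out


def merge_whisker_candidates(
    candidates: list[MovementEvent], merge_gap: float = 0.1
) -> list[MovementEvent]:
    """Collapse runs of whisker candidates closer than ``merge_gap``.

    Whisker protraction/retraction cycles lack clean boundaries, so only
    the first twitch of a rapid series is counted.
    """
    out: list[MovementEvent] = []
    for ev in sort_events(candidates):
        if ev.body_part != "whiskers":
            out.append(ev)
            continue
        prev = next((e for e in reversed(out) if e.body_part == "whiskers"), None)
        if prev is None or ev.onset - prev.onset >= merge_gap:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# behavioral state classification

def classify_states(
    times: np.ndarray,
    nuchal_tone: np.ndarray,
    delta_power: np.ndarray,
    twitch_events: list[MovementEvent] | None = None,
    movement_events: list[MovementEvent] | None = None,
    config: AnalysisConfig | None = None,
) -> StateTimeline:
    """Rule-based sleep/wake scoring on shared-time-base feature traces.

    Rule order: REM = atonia (tone below its atonia quantile) with twitching
    in the bout; NREM = high delta power with behavioral quiescence;
    everything else is wake. Wake samples within 3 s after a movement onset
    become active wake, the rest quiet wake.
    """
    config = config or AnalysisConfig()
    times = np.asarray(times, dtype=float)
    nuchal_tone = np.asarray(nuchal_tone, dtype=float)
    delta_power = np.asarray(delta_power, dtype=float)
    if not (times.size == nuchal_tone.size == delta_power.size):
        raise AlignmentError("state feature traces must share one time base")
    if times.size < 2:
        raise InvalidParameterError("need at least two samples to score states")

    twitch_onsets = np.array(
        sorted(e.onset for e in (twitch_events or [])), dtype=float
    )
    move_onsets = np.array(
        sorted(e.onset for e in (movement_events or [])), dtype=float
    )

    atonia_thr = np.quantile(nuchal_tone, config.atonia_quantile)
    delta_thr = np.quantile(delta_power, config.delta_quantile)
    # strict comparisons so constant (degenerate) traces trigger neither rule
    atonia = nuchal_tone < atonia_thr
    high_delta = delta_power > delta_thr

    dt = float(np.median(np.diff(times)))
    # behavioral quiescence: no movement onset within the sample
    quiescent = np.ones(times.size, dtype=bool)
    if move_onsets.size:
        idx = np.searchsorted(times, move_onsets) - 1
        idx = idx[(idx >= 0) & (idx < times.size)]
        quiescent[idx] = False

    labels = np.full(times.size, "quiet_wake", dtype=object)
    # REM: atonia bouts that contain twitching
    bouts = _runs(atonia)
    for s, e in bouts:
        t_lo, t_hi = times[s], times[e - 1] + dt
        has_twitch = bool(
            twitch_onsets.size
            and np.any((twitch_onsets >= t_lo) & (twitch_onsets < t_hi))
        )
        if has_twitch:
            labels[s:e] = "REM"
    # NREM: high delta with quiescence, not already REM
    nrem = high_delta & quiescent & (labels != "REM")
    labels[nrem] = "NREM"
    # active wake: within 3 s after a movement
    if move_onsets.size:
        wake_mask = (labels == "quiet_wake")
        after = np.zeros(times.size, dtype=bool)
        for onset in move_onsets:
            after |= (times >= onset) & (times < onset + config.active_wake_window_s)
        labels[wake_mask & after] = "active_wake"

    intervals: list[tuple[float, float, str]] = []
    start = times[0]
    for i in range(1, times.size):
        if labels[i] != labels[i - 1]:
            intervals.append((start, times[i], str(labels[i - 1])))
            start = times[i]
    intervals.append((start, times[-1] + dt, str(labels[-1])))
    return StateTimeline(intervals)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    if not mask.any():
        return []
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# EMG rules

def emg_event_inclusion(
    emg_times: np.ndarray,
    rectified_emg: np.ndarray,
    events: list[MovementEvent],
    z_threshold: float = 2.0,
    baseline_window: tuple[float, float] = (-1.0, -0.2),
    response_window: tuple[float, float] = (0.0, 0.25),
) -> np.ndarray:
    """Mask of events whose rectified EMG reaches the z threshold.

    Per event, the EMG baseline mean/SD come from ``baseline_window``
    relative to onset; the event is included when the peri-event peak z
    (within ``response_window``) is >= ``z_threshold`` (inclusive). Events
    with zero baseline SD are excluded with a warning.
    """
    emg_times = np.asarray(emg_times, dtype=float)
    rectified_emg = np.asarray(rectified_emg, dtype=float)
    mask = np.zeros(len(events), dtype=bool)
    for i, ev in enumerate(events):
        b = (emg_times >= ev.onset + baseline_window[0]) & (emg_times < ev.onset + baseline_window[1])
        r = (emg_times >= ev.onset + response_window[0]) & (emg_times < ev.onset + response_window[1])
        if not b.any() or not r.any():
            continue
        mu, sd = rectified_emg[b].mean(), rectified_emg[b].std()
        if sd == 0:
            logger.warning("event at %.3f s: zero EMG baseline SD; excluded", ev.onset)
            continue
        peak_z = (rectified_emg[r].max() - mu) / sd
        mask[i] = peak_z >= z_threshold
    return mask


def grand_mean_emg(per_animal_profiles: dict[str, np.ndarray]) -> np.ndarray:
    """Two-stage grand mean: within-animal mean first, then across animals.

    ``per_animal_profiles`` maps animal id to an (n_events, n_samples)
    array (or an already-averaged 1-D profile). Animals contribute equally
    regardless of their event counts.
    """
    if not per_animal_profiles:
        raise EmptyResultError("no animals with included events")
    means = []
    for animal, profiles in per_animal_profiles.items():
        arr = np.asarray(profiles, dtype=float)
        if arr.size == 0:
            raise EmptyResultError(f"animal {animal} has zero included events")
        means.append(arr.mean(axis=0) if arr.ndim == 2 else arr)
    lengths = {m.size for m in means}
    if len(lengths) != 1:
        raise AlignmentError("per-animal EMG profiles differ in length")
    return np.mean(means, axis=0)
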