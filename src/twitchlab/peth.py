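"""Perievent time histograms and movement-active classification.

A PETH counts each neuron's spikes in 10 ms bins over a -3..3 s window
around every movement onset (600 bins at defaults, half-open bins). The
trial-mean trace is z-scored against its own baseline bins (-3..-0.5 s):
z = (mean - baseline mean) / baseline SD, where the SD is taken across
baseline bins of the mean trace. A neuron is movement-active when its
z-trace reaches at least 3.5 inside the class window (-100..250 ms for
twitches, -100..500 ms for wake movements) and it has strictly more than
20 events; the preferred body part is the one with the largest
super-threshold peak among isolated twitches.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import AnalysisConfig
from .errors import EmptyResultError, InvalidParameterError
from .types import MovementEvent, NeuronClassification, Peth, PixelChangeSeries, SpikeTrain

logger = logging.getLogger(__name__)

#: classification outcomes
ACTIVE = "active"
INACTIVE = "inactive"
INSUFFICIENT_EVENTS = "insufficient_events"
UNCLASSIFIABLE = "unclassifiable"


def build_peth(
    spikes: SpikeTrain,
    events: list[MovementEvent] | np.ndarray,
    window: tuple[float, float] = (-3.0, 3.0),
    bin_size: float = 0.010,
    baseline_window: tuple[float, float] = (-3.0, -0.5),
) -> Peth:
    """Event-aligned spike-count matrix with half-open bins.

    ``counts[i, j]`` is the number of spikes in
    ``[onset_i + edges[j], onset_i + edges[j+1})``.
    """
    if isinstance(events, np.ndarray):
        onsets = events.astype(float)
    else:
        onsets = np.asarray(
            [e.onset if isinstance(e, MovementEvent) else e for e in events],
            dtype=float,
        )
    if onsets.size == 0:
        raise EmptyResultError("cannot build a perievent histogram from zero events")
    lo, hi = window
    n_bins = (hi - lo) / bin_size
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise InvalidParameterError(f"bin size {bin_size} must divide window {window} evenly")
    n_bins = int(round(n_bins))
    edges = lo + np.arange(n_bins + 1) * bin_size
    # one vectorized searchsorted over every event's absolute edge positions
    abs_edges = (onsets[:, None] + edges[None, :]).ravel()
    pos = np.searchsorted(spikes.spike_times, abs_edges, side="left")
    pos = pos.reshape(onsets.size, n_bins + 1)
    counts = np.diff(pos, axis=1)
    return Peth(
        counts=counts, bin_edges=edges, n_events=int(onsets.size),
        baseline_window=baseline_window,
    )


def zscore_peth(p: Peth) -> Peth:
    """Fill in baseline statistics and the z-scored mean trace, in place.

    Baseline mean and SD are computed across the baseline bins of the
    trial-mean trace. A zero baseline SD leaves ``z_trace`` undefined
    (``None``); such a neuron is unclassifiable.
    """
    mask = p.baseline_bin_mask()
    if not mask.any():
        raise InvalidParameterError("baseline window contains no bins")
    mean_trace = p.mean_trace
    p.baseline_mean = float(mean_trace[mask].mean())
    p.baseline_sd = float(mean_trace[mask].std())
    if p.baseline_sd == 0:
        logger.warning("baseline SD is 0; z-trace undefined (unclassifiable)")
        p.z_trace = None
    else:
        p.z_trace = (mean_trace - p.baseline_mean) / p.baseline_sd
    return p


def _window_mask(p: Peth, window: tuple[float, float]) -> np.ndarray:
    c = p.bin_centers
    return (c >= window[0]) & (c < window[1])


def classify_movement_active(
    p: Peth,
    movement_class: str = "twitch",
    config: AnalysisConfig | None = None,
) -> tuple[str, float | None]:
    """Movement-active test: peak z >= threshold inside the class window.

    Returns ``(status, peak_z)`` where status is one of ``active``,
    ``inactive``, ``insufficient_events`` or ``unclassifiable``. Fewer than
    the minimum number of events (strictly more than 20 required) yields
    ``insufficient_events`` rather than "inactive".
    """
    config = config or AnalysisConfig()
    if movement_class == "twitch":
        window = config.twitch_class_window_s
    elif movement_class == "wake":
        window = config.wake_class_window_s
    else:
        raise InvalidParameterError(f"unknown movement class {movement_class!r}")
    if p.n_events < config.min_events:
        return INSUFFICIENT_EVENTS, None
    if p.z_trace is None:
        zscore_peth(p)
    if p.z_trace is None:
        return UNCLASSIFIABLE, None
    peak = float(np.max(p.z_trace[_window_mask(p, window)]))
    return (ACTIVE if peak >= config.z_threshold else INACTIVE), peak


def preferred_body_part(
    peths_by_part: dict[str, Peth],
    config: AnalysisConfig | None = None,
) -> tuple[str | None, dict[str, float]]:
    """Body part with the largest super-threshold twitch-window peak.

    Expects PETHs built on *isolated* twitches (cross-body-part mode).
    Returns ``(label_or_None, peak_z_by_part)``; parts with too few events
    or undefined z are omitted from the peak map. Ties break toward the
    earlier peak time, then lexically (and are logged).
    """
    config = config or AnalysisConfig()
    peaks: dict[str, float] = {}
    candidates: list[tuple[float, float, str]] = []  # (-peak, peak_time, part)
    for part in sorted(peths_by_part):
        p = peths_by_part[part]
        status, peak = classify_movement_active(p, "twitch", config)
        if peak is None:
            continue
        peaks[part] = peak
        if status == ACTIVE:
            mask = _window_mask(p, config.twitch_class_window_s)
            centers = p.bin_centers[mask]
            z = p.z_trace[mask]
            peak_time = float(centers[int(np.argmax(z))])
            candidates.append((-peak, peak_time, part))
    if not candidates:
        return None, peaks
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        logger.info("preferred body part tie between %s and %s; earlier peak wins",
                    candidates[0][2], candidates[1][2])
    return candidates[0][2], peaks


def classify_neuron(
    spikes: SpikeTrain,
    twitch_events_by_part: dict[str, list[MovementEvent]],
    wake_events: list[MovementEvent],
    config: AnalysisConfig | None = None,
) -> NeuronClassification:
    """Full movement-activity classification of one neuron.

    A neuron is twitch-active if any body part with enough isolated
    twitches passes the z >= 3.5 test in the twitch window; wake-active is
    the same test on wake-movement PETHs in the wake window.
    """
    config = config or AnalysisConfig()
    out = NeuronClassification(neuron_id=spikes.neuron_id)
    peths: dict[str, Peth] = {}
    statuses = []
    for part, events in twitch_events_by_part.items():
        out.n_events_by_body_part[part] = len(events)
        if not events:
            continue
        p = zscore_peth(build_peth(
            spikes, events, config.peth_window_s, config.bin_size_s,
            config.baseline_window_s,
        ))
        peths[part] = p
        status, _peak = classify_movement_active(p, "twitch", config)
        statuses.append(status)
    out.twitch_active = ACTIVE in statuses
    if statuses:
        out.twitch_status = ACTIVE if out.twitch_active else (
            INACTIVE if INACTIVE in statuses else statuses[0])
    preferred, peaks = preferred_body_part(peths, config)
    out.preferred_body_part = preferred
    out.peak_z_by_body_part = peaks

    if wake_events:
        p = zscore_peth(build_peth(
            spikes, wake_events, config.peth_window_s, config.bin_size_s,
            config.baseline_window_s,
        ))
        out.wake_status, _ = classify_movement_active(p, "wake", config)
        out.wake_active = out.wake_status == ACTIVE
        out.n_events_by_body_part["wake"] = len(wake_events)
    return out


def median_displacement_profile(
    series: PixelChangeSeries,
    events: list[MovementEvent],
    window: tuple[float, float] = (-0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Event-triggered median displacement, normalized to its maximum.

    For one animal: the median of the ROI series across events at each
    perievent time point, divided by its own maximum so the profile peaks
    at exactly 1. Expects isolated events (same-body-part mode). Returns
    ``(lags_s, profile)``.
    """
    if not events:
        raise EmptyResultError("median displacement profile needs at least one event")
    fr = series.frame_rate
    lo = int(round(window[0] * fr))
    hi = int(round(window[1] * fr))
    lags = np.arange(lo, hi) / fr
    rows = []
    for ev in events:
        i0 = int(round((ev.onset - series.start_time) * fr))
        if i0 + lo < 0 or i0 + hi > series.values.size:
            continue
        rows.append(series.values[i0 + lo: i0 + hi])
    if not rows:
        raise EmptyResultError("no event window fits inside the series")
    profile = np.median(np.asarray(rows, dtype=float), axis=0)
    peak = profile.max()
    if peak > 0:
        profile = profile / peak
    return lags, profile


def cross_animal_mean_profile(per_animal: list[np.ndarray]) -> np.ndarray:
    """Average per-animal normalized profiles (each already peaking at 1)."""
    if not per_animal:
        raise EmptyResultError("no animals provided")
    return np.mean(np.asarray(per_animal, dtype=float), axis=0)
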