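"""Temporal response metrics per neuron.

Peak latency is the bin-center time of the z-trace maximum in the response
window (ties break to the earlier bin). Width at half-height follows the
fixed pipeline: 5-bin moving-average smoothing, linear interpolation from
10 ms to 1 ms bins, affine normalization (baseline -> 0, peak -> 1), then
the count of contiguous 1 ms bins above 0.5 around the peak. The
premovement proportion divides the trapezoidal integral of the z-trace
before onset by the integral of the whole analysis window (twitches:
-0.2..0 over -0.2..0.2 s, or -0.2..0.75 s for developmental comparisons;
wake movements re-zero at the smoothed pre-onset minimum and integrate from
that minimum to +1 s). Negative numerators clamp to 0. The Fano factor is
the sample variance over mean of per-event spike counts in the activity
window (-70..70 ms twitches, -100..500 ms wake).
"""

from __future__ import annotations

import logging

import numpy as np

from .config import AnalysisConfig
from .errors import InsufficientDataError, InvalidParameterError
from .types import MovementEvent, Peth, SpikeTrain, StateTimeline, event_onsets

logger = logging.getLogger(__name__)


def _z_or_raise(p: Peth) -> np.ndarray:
    if p.z_trace is None:
        raise InvalidParameterError("peth has no z-trace; run zscore_peth first")
    return p.z_trace


def peak_latency(
    p: Peth, response_window: tuple[float, float] = (-0.1, 0.25)
) -> float:
    """Bin-center time (ms) of the z-trace maximum within the window."""
    z = _z_or_raise(p)
    c = p.bin_centers
    mask = (c >= response_window[0]) & (c < response_window[1])
    if not mask.any():
        raise InvalidParameterError("response window contains no bins")
    zw = z[mask]
    i = int(np.argmax(zw))  # argmax returns the first (earliest) maximum
    return float(c[mask][i] * 1000.0)


def moving_average(trace: np.ndarray, n_bins: int) -> np.ndarray:
    """Boxcar smoothing with edge-shrinking normalization ('same' length)."""
    kernel = np.ones(n_bins)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den


def width_from_trace(
    trace: np.ndarray,
    bin_size_ms: float,
    baseline_value: float,
    smooth_bins: int = 5,
    peak_index: int | None = None,
) -> float:
    """Width at half-height of a response trace, in ms.

    Helper entry point used on any per-bin trace: smooth (boxcar), upscale
    to a 1 ms grid by linear interpolation, normalize so baseline maps to 0
    and the peak to 1, then count the contiguous run of 1 ms bins > 0.5
    containing the peak.
    """
    trace = np.asarray(trace, dtype=float)
    sm = moving_average(trace, smooth_bins) if smooth_bins > 1 else trace
    centers_ms = np.arange(trace.size) * bin_size_ms
    fine = np.arange(0.0, centers_ms[-1] + 1e-9, 1.0)
    up = np.interp(fine, centers_ms, sm)
    if peak_index is None:
        i_peak = int(np.argmax(up))
    else:
        i_peak = int(round(peak_index * bin_size_ms))
    peak = up[i_peak]
    if peak <= baseline_value:
        raise InvalidParameterError("peak does not exceed baseline; width undefined")
    norm = (up - baseline_value) / (peak - baseline_value)
    above = norm > 0.5
    lo = i_peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    return float(hi - lo + 1)


def width_at_half_height(
    p: Peth,
    config: AnalysisConfig | None = None,
) -> float:
    """Width at half-height (ms) of a neuron's z-scored perievent response."""
    config = config or AnalysisConfig()
    z = _z_or_raise(p)
    return width_from_trace(
        z, p.bin_size * 1000.0, baseline_value=0.0,
        smooth_bins=config.whh_smooth_bins,
    )


def _trapz_between(p: Peth, z: np.ndarray, lo: float, hi: float,
                   offset: float = 0.0) -> float:
    """Trapezoidal integral of the piecewise-linear z-trace over [lo, hi].

    Endpoints are evaluated by linear interpolation between bin centers so
    bounds falling between centers (onset in particular) are respected
    exactly.
    """
    c = p.bin_centers
    lo_c, hi_c = max(lo, float(c[0])), min(hi, float(c[-1]))
    if not hi_c > lo_c:
        raise InvalidParameterError("integration window spans no bins")
    interior = c[(c > lo_c) & (c < hi_c)]
    xs = np.concatenate([[lo_c], interior, [hi_c]])
    ys = np.interp(xs, c, z) - offset
    return float(np.trapezoid(ys, xs))


def premove_proportion_twitch(
    p: Peth,
    analysis_window: tuple[float, float] = (-0.2, 0.2),
) -> float | None:
    """Fraction of integrated twitch-triggered z-activity before onset.

    Trapezoidal integrals of the z-trace: numerator over [-0.2, 0] s,
    denominator over the full analysis window. A negative numerator is
    clamped to 0; a non-positive denominator leaves the proportion
    undefined (None, neuron excluded with a log message).
    """
    z = _z_or_raise(p)
    lo, hi = analysis_window
    total = _trapz_between(p, z, lo, hi)
    if total <= 0:
        logger.warning("non-positive total integral; premovement proportion undefined")
        return None
    num = _trapz_between(p, z, lo, 0.0)
    return float(np.clip(num / total, 0.0, 1.0))


def premove_proportion_wake(
    p: Peth,
    config: AnalysisConfig | None = None,
) -> float | None:
    """Premovement proportion for wake movements with an adjusted baseline.

    The baseline is the minimum, within the 500 ms preceding onset, of the
    perievent histogram smoothed with a 20-bin kernel; the integration
    window runs from the time of that minimum to 1 s after onset, with the
    minimum's value subtracted before integrating.
    """
    config = config or AnalysisConfig()
    z = _z_or_raise(p)
    c = p.bin_centers
    sm = moving_average(z, config.wake_baseline_smooth_bins)
    pre = (c >= -config.premove_wake_lookback_s) & (c < 0.0)
    if not pre.any():
        raise InvalidParameterError("no bins in the 500 ms preceding onset")
    i_min = np.flatnonzero(pre)[int(np.argmin(sm[pre]))]
    t_min = float(c[i_min])
    adjusted = float(sm[i_min])
    total = _trapz_between(p, z, t_min, config.premove_wake_extent_s, offset=adjusted)
    if total <= 0:
        logger.warning("non-positive adjusted total integral; premovement proportion undefined")
        return None
    num = _trapz_between(p, z, t_min, 0.0, offset=adjusted)
    return float(np.clip(num / total, 0.0, 1.0))


def spike_counts_in_window(
    spikes: SpikeTrain,
    events: list[MovementEvent] | np.ndarray,
    window: tuple[float, float],
) -> np.ndarray:
    """Per-event spike counts in the half-open window around each onset."""
    onsets = event_onsets(events) if events and isinstance(events[0], MovementEvent) \
        else np.asarray(events, dtype=float)
    lo = np.searchsorted(spikes.spike_times, onsets + window[0], side="left")
    hi = np.searchsorted(spikes.spike_times, onsets + window[1], side="left")
    return hi - lo


def fano_factor(
    spikes: SpikeTrain,
    events: list[MovementEvent] | np.ndarray,
    window: tuple[float, float] = (-0.07, 0.07),
) -> float | None:
    """Variance-to-mean ratio of spike counts in the activity window.

    Sample variance uses the n-1 denominator. A zero mean count leaves the
    Fano factor undefined (None, logged); fewer than two events raise.
    """
    counts = spike_counts_in_window(spikes, events, window)
    if counts.size < 2:
        raise InsufficientDataError("Fano factor needs at least two events")
    mean = counts.mean()
    if mean == 0:
        logger.warning("zero mean spike count; Fano factor undefined")
        return None
    return float(counts.var(ddof=1) / mean)


def baseline_rate_by_state(
    spikes: SpikeTrain, timeline: StateTimeline
) -> dict[str, float]:
    """Spikes/s per behavioral state: counts in state intervals / duration.

    Spikes outside every interval are counted in no state. States with zero
    total duration are omitted (rate undefined).
    """
    rates: dict[str, float] = {}
    counts: dict[str, int] = {}
    durations = timeline.duration_by_state()
    for start, end, state in timeline.intervals:
        lo = np.searchsorted(spikes.spike_times, start, side="left")
        hi = np.searchsorted(spikes.spike_times, end, side="left")
        counts[state] = counts.get(state, 0) + int(hi - lo)
    for state, dur in durations.items():
        if dur > 0:
            rates[state] = counts.get(state, 0) / dur
    return rates
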