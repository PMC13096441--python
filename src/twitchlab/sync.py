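"""Frame-clock validation and repair against LED sync pulses.

An LED in the camera's view pulses on a fixed interval (default every 3 s),
so at 100 frames/s every inter-pulse gap must contain exactly 300 frames.
Gaps with fewer frames indicate dropped frames; a "dummy frame" is inserted
per missing frame so that frame indices stay aligned with recording time to
within one frame (10 ms at the default rate).

Dummies for a deficit-``d`` gap are spaced evenly between the last observed
frame of that gap and the gap end; observed timestamps are never moved.
With at most one drop per gap (the realistic, infrequent-drop regime) every
frame index then stays within one frame of its pulse-linear position; a gap
that lost d frames can drift by up to d frames for the frames following
the drops, since the true drop positions inside a gap are unknowable.
Gaps with surplus frames cannot be repaired and raise
:class:`~twitchlab.errors.UnrecoverableClockError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UnrecoverableClockError
from .types import FrameClock

logger = logging.getLogger(__name__)


def expected_interpulse_frames(frame_rate: float, pulse_interval: float) -> int:
    """Exact number of frames expected between consecutive LED pulses.

    ``pulse_interval * frame_rate`` must be an integer (within 1e-9);
    non-integer products are a configuration error.
    """
    if frame_rate <= 0 or pulse_interval <= 0:
        raise ConfigError("frame_rate and pulse_interval must be > 0")
    product = frame_rate * pulse_interval
    if abs(product - round(product)) > 1e-9:
        raise ConfigError(
            f"pulse_interval x frame_rate = {product} is not an integer;"
            " frames cannot be validated against pulses"
        )
    return int(round(product))


@dataclass(frozen=True)
class GapReport:
    """One inter-pulse gap: observed frame count and its deficit."""

    gap_index: int
    observed_frames: int
    deficit: int  # expected - observed; negative = surplus


def validate_frame_intervals(clock: FrameClock) -> list[GapReport]:
    """Count frames in each half-open inter-pulse gap ``[p_k, p_{k+1})``.

    Returns one record per gap; with fewer than two pulses an empty report
    is returned with a warning (nothing can be validated).
    """
    if clock.pulse_times.size < 2:
        logger.warning("frame clock has %d pulse(s); cannot validate intervals",
                       clock.pulse_times.size)
        return []
    expected = expected_interpulse_frames(clock.frame_rate, clock.pulse_interval)
    idx = np.searchsorted(clock.frame_times, clock.pulse_times, side="left")
    return [
        GapReport(gap_index=k, observed_frames=int(idx[k + 1] - idx[k]),
                  deficit=int(expected - (idx[k + 1] - idx[k])))
        for k in range(clock.pulse_times.size - 1)
    ]


def repair_frame_clock(clock: FrameClock) -> FrameClock:
    """Insert dummy frames so every inter-pulse gap has the expected count.

    Idempotent: repairing an already-repaired clock is the identity. A gap
    with surplus frames (negative deficit) is unrecoverable.
    """
    report = validate_frame_intervals(clock)
    if all(r.deficit == 0 for r in report):
        return clock

    surplus = [r for r in report if r.deficit < 0]
    if surplus:
        raise UnrecoverableClockError(
            f"gap(s) {[r.gap_index for r in surplus]} contain surplus frames;"
            " clock cannot be repaired by dummy insertion"
        )

    frame_times = list(clock.frame_times)
    dummy = list(clock.dummy_flags)
    # walk gaps from the end so earlier insert positions stay valid
    idx = np.searchsorted(clock.frame_times, clock.pulse_times, side="left")
    for rec in reversed(report):
        if rec.deficit == 0:
            continue
        k = rec.gap_index
        i0, i1 = int(idx[k]), int(idx[k + 1])
        gap_end = float(clock.pulse_times[k + 1])
        last = frame_times[i1 - 1] if i1 > i0 else float(clock.pulse_times[k])
        d = rec.deficit
        new_times = [last + (gap_end - last) * (j + 1) / (d + 1) for j in range(d)]
        frame_times[i1:i1] = new_times
        dummy[i1:i1] = [True] * d
        logger.info("gap %d: inserted %d dummy frame(s)", k, d)

    repaired = FrameClock(
        frame_times=np.asarray(frame_times), pulse_times=clock.pulse_times,
        frame_rate=clock.frame_rate, pulse_interval=clock.pulse_interval,
        dummy_flags=np.asarray(dummy, dtype=bool),
    )
    # post-condition: all deficits now zero
    assert all(r.deficit == 0 for r in validate_frame_intervals(repaired))
    return repaired


def frame_index_to_time(clock: FrameClock, indices: np.ndarray) -> np.ndarray:
    """Map (repaired) frame indices to electrophysiology time."""
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= clock.n_frames):
        raise IndexError("frame index out of range for clock")
    return clock.frame_times[indices]
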