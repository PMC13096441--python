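"""Readers and writers for the package's tabular formats.

All tables are RFC-4180 CSV with a header row. Spike tables carry
``neuron_id,time_s``; event tables ``onset_s,body_part,class,state``; state
timelines are BED-like ``start_s,end_s,state`` interval tables; frame clocks
``frame_time_s,dummy_flag`` plus a pulse list. Pose tables use the 3-row
header dialect (scorer / bodyparts / coords) produced by markerless
tracking tools, with per-bodypart x, y and likelihood columns.

Writers and readers satisfy a closure property: every file a writer
produces is accepted by the corresponding reader and round-trips the data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, load_config  # noqa: F401  (re-exported)
from .errors import FormatError
from .types import (
    MOVEMENT_CLASSES,
    FrameClock,
    MovementEvent,
    PixelChangeSeries,
    SpikeTrain,
    StateTimeline,
    Trajectory,
    sort_events,
)

logger = logging.getLogger(__name__)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _check_no_nan(values: np.ndarray, what: str, path) -> None:
    if np.any(np.isnan(values)):
        raise FormatError(f"{path}: NaN {what} not allowed")


# ---------------------------------------------------------------------------
# spike tables

def read_spike_table(path, session_span: tuple[float, float] | None = None) -> list[SpikeTrain]:
    """Read ``neuron_id,time_s`` rows into one SpikeTrain per neuron.

    Times are sorted on load (with a warning if the file was unsorted).
    When ``session_span`` is omitted it is inferred as [0, max time + 1 s).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("neuron_id", "time_s"), path)
    if df.empty:
        return []
    _check_no_nan(df["time_s"].to_numpy(float), "spike time", path)
    trains = []
    for neuron_id, sub in df.groupby("neuron_id", sort=True):
        times = sub["time_s"].to_numpy(float)
        if np.any(np.diff(times) < 0):
            logger.warning("spike table %s: times for %s unsorted; sorting", path, neuron_id)
            times = np.sort(times)
        span = session_span if session_span is not None else (0.0, float(times[-1]) + 1.0)
        region = str(sub["region"].iloc[0]) if "region" in sub.columns else ""
        trains.append(
            SpikeTrain(neuron_id=str(neuron_id), spike_times=times,
                       session_span=span, region_label=region)
        )
    return trains


def write_spike_table(trains: list[SpikeTrain], path) -> None:
    frames = [
        pd.DataFrame({
            "neuron_id": t.neuron_id,
            "time_s": t.spike_times,
            "region": t.region_label,
        })
        for t in trains
    ]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["neuron_id", "time_s", "region"]))
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# event tables

_EVENT_COLS = ("onset_s", "body_part", "class", "state")


def read_event_table(path) -> list[MovementEvent]:
    """Read a movement-event table; events are sorted by onset on load."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _EVENT_COLS, path)
    if df.empty:
        return []
    _check_no_nan(df["onset_s"].to_numpy(float), "onset", path)
    bad = set(df["class"]) - set(MOVEMENT_CLASSES)
    if bad:
        raise FormatError(
            f"{path}: unknown movement class label(s) {sorted(bad)};"
            f" allowed: {list(MOVEMENT_CLASSES)}"
        )
    amps = df["amplitude_mm"] if "amplitude_mm" in df.columns else [None] * len(df)
    angs = df["angle_deg"] if "angle_deg" in df.columns else [None] * len(df)
    events = []
    for onset, part, cls, state, amp, ang in zip(
        df["onset_s"], df["body_part"], df["class"], df["state"], amps, angs
    ):
        events.append(
            MovementEvent(
                onset=float(onset), body_part=str(part), movement_class=str(cls),
                state=None if pd.isna(state) else str(state),
                amplitude_mm=None if amp is None or pd.isna(amp) else float(amp),
                angle_deg=None if ang is None or pd.isna(ang) else float(ang),
            )
        )
    return sort_events(events)


def write_event_table(events: list[MovementEvent], path) -> None:
    events = sort_events(events)
    df = pd.DataFrame({
        "onset_s": [e.onset for e in events],
        "body_part": [e.body_part for e in events],
        "class": [e.movement_class for e in events],
        "state": [e.state if e.state is not None else "" for e in events],
        "amplitude_mm": [e.amplitude_mm for e in events],
        "angle_deg": [e.angle_deg for e in events],
    })
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# state timelines (BED-like interval table)

def read_state_timeline(path) -> StateTimeline:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("start_s", "end_s", "state"), path)
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.state))
        for r in df.itertuples(index=False)
    ]
    return StateTimeline(intervals)


def write_state_timeline(timeline: StateTimeline, path) -> None:
    df = pd.DataFrame(timeline.intervals, columns=["start_s", "end_s", "state"])
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pose tables (3-row header dialect)

def read_pose_table(
    path,
    calibration: float = 5.75,
    frame_rate: float = 100.0,
    frame_clock: FrameClock | None = None,
) -> list[Trajectory]:
    """Read a pose CSV with the scorer/bodyparts/coords 3-row header.

    One Trajectory per body part; frame index is row order. Frame times come
    from the non-dummy frames of ``frame_clock`` when given (each pose row
    is one captured video frame), otherwise from ``frame_rate``. A missing
    likelihood column is filled with 1.0 and logged. ``calibration`` (px/mm)
    is stored on every trajectory.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed 3-row pose header ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    n = len(df)
    if frame_clock is not None:
        real = frame_clock.real_frame_times()
        if real.size < n:
            raise FormatError(
                f"{path}: {n} pose rows but frame clock has only {real.size} captured frames"
            )
        times = real[:n]
    else:
        times = np.arange(n) / frame_rate

    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    out = []
    for part in bodyparts:
        sub = df.xs(part, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y"):
            if coord not in sub.columns:
                raise FormatError(f"{path}: bodypart {part!r} lacks {coord!r} column")
        if "likelihood" in sub.columns:
            likelihood = sub["likelihood"].to_numpy(float)
        else:
            logger.warning("pose table %s: %s has no likelihood column; filling 1.0", path, part)
            likelihood = np.ones(n)
        out.append(
            Trajectory(
                bodypart=str(part), times=times,
                x=sub["x"].to_numpy(float), y=sub["y"].to_numpy(float),
                likelihood=likelihood, calibration=calibration,
            )
        )
    return out


def write_pose_table(trajectories: list[Trajectory], path, scorer: str = "twitchlab") -> None:
    """Write trajectories in the 3-row-header pose dialect."""
    cols = {}
    for traj in trajectories:
        cols[(scorer, traj.bodypart, "x")] = traj.x
        cols[(scorer, traj.bodypart, "y")] = traj.y
        cols[(scorer, traj.bodypart, "likelihood")] = traj.likelihood
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    df.index.name = None
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# frame clocks, series, ground truth

def read_frame_clock(frames_path, pulses_path, frame_rate: float, pulse_interval: float) -> FrameClock:
    fdf = pd.read_csv(frames_path, float_precision="round_trip")
    _require_columns(fdf, ("frame_time_s",), frames_path)
    pdf = pd.read_csv(pulses_path, float_precision="round_trip")
    _require_columns(pdf, ("pulse_time_s",), pulses_path)
    dummy = (fdf["dummy_flag"].to_numpy(bool)
             if "dummy_flag" in fdf.columns else None)
    return FrameClock(
        frame_times=fdf["frame_time_s"].to_numpy(float),
        pulse_times=pdf["pulse_time_s"].to_numpy(float),
        frame_rate=frame_rate, pulse_interval=pulse_interval,
        dummy_flags=dummy,
    )


def write_frame_clock(clock: FrameClock, frames_path, pulses_path) -> None:
    pd.DataFrame({
        "frame_time_s": clock.frame_times,
        "dummy_flag": clock.dummy_flags.astype(int),
    }).to_csv(frames_path, index=False, float_format="%.17g")
    pd.DataFrame({"pulse_time_s": clock.pulse_times}).to_csv(pulses_path, index=False, float_format="%.17g")


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a generic (time, value) CSV series."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time_s", "value"), path)
    t = df["time_s"].to_numpy(float)
    _check_no_nan(t, "time", path)
    return t, df["value"].to_numpy(float)


def write_series(times: np.ndarray, values: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": times, "value": values}).to_csv(path, index=False, float_format="%.17g")


def write_pixel_series(series: PixelChangeSeries, path) -> None:
    write_series(series.times(), series.values, path)


def write_ground_truth(ground_truth, path) -> None:
    """Structured-text (JSON) sidecar with the generator's ground truth."""
    gt = {
        "event_onsets": [e.onset for e in ground_truth.events],
        "event_body_parts": [e.body_part for e in ground_truth.events],
        "event_classes": [e.movement_class for e in ground_truth.events],
        "event_amplitudes_mm": [e.amplitude_mm for e in ground_truth.events],
        "event_angles_deg": [e.angle_deg for e in ground_truth.events],
        "dropped_frame_indices": np.asarray(ground_truth.dropped_frame_indices).tolist(),
        "neuron_truth": ground_truth.neuron_truth,
        "pixel_pulses": {k: [list(s) for s in v] for k, v in ground_truth.pixel_pulses.items()},
    }
    Path(path).write_text(json.dumps(gt, indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
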