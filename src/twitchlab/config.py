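"""Analysis configuration.

Every constant of the analysis lives in :class:`AnalysisConfig` with the
defaults used throughout: 10 ms bins over a -3..3 s perievent window,
baseline -3..-0.5 s, z threshold 3.5, twitch/wake classification windows
-100..250 ms and -100..500 ms, 100 ms twitch isolation, 500 ms wake
quiescence, Fano windows -70..70 ms (twitch) and -100..500 ms (wake),
150/500 ms kinematic windows, 12 direction bins, 0.1 selectivity threshold,
5.75 px/mm camera calibration, 5% pixel-change threshold at 100 frames/s,
3 s LED pulse interval and a MAD factor of 3 for outlier flagging.

Configs are plain dataclasses loadable from YAML via :func:`load_config`;
unknown keys and out-of-range values raise :class:`~twitchlab.errors.ConfigError`
naming the offending key.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

Window = tuple[float, float]


@dataclass
class AnalysisConfig:
    # perievent histogram
    bin_size_s: float = 0.010
    peth_window_s: Window = (-3.0, 3.0)
    baseline_window_s: Window = (-3.0, -0.5)
    z_threshold: float = 3.5
    twitch_class_window_s: Window = (-0.100, 0.250)
    wake_class_window_s: Window = (-0.100, 0.500)
    #: movement-active classification requires strictly more than 20 events
    min_events: int = 21

    # behavioral scoring
    isolation_window_s: float = 0.100
    wake_quiescence_s: float = 0.500
    whisker_merge_gap_s: float = 0.100
    pixel_change_threshold: float = 0.05
    roi_threshold_mad_factor: float = 3.0
    #: bouts shorter than this many frames are treated as sensor noise
    roi_min_bout_frames: int = 2
    atonia_quantile: float = 0.20
    delta_quantile: float = 0.70
    active_wake_window_s: float = 3.0
    emg_z_threshold: float = 2.0

    # temporal metrics
    fano_window_twitch_s: Window = (-0.070, 0.070)
    fano_window_wake_s: Window = (-0.100, 0.500)
    whh_smooth_bins: int = 5
    wake_baseline_smooth_bins: int = 20
    premove_window_twitch_s: Window = (-0.200, 0.200)
    premove_window_development_s: Window = (-0.200, 0.750)
    premove_wake_lookback_s: float = 0.500
    premove_wake_extent_s: float = 1.000

    # kinematics
    kinematic_window_twitch_s: float = 0.150
    kinematic_window_wake_s: float = 0.500
    n_direction_bins: int = 12
    selectivity_threshold: float = 0.1
    calibration_px_per_mm: float = 5.75
    angle_mode: str = "at_peak"  # or "path_mean"
    likelihood_flag_threshold: float = 0.85
    activity_window_twitch_s: Window = (-0.070, 0.070)
    activity_window_wake_s: Window = (-0.100, 0.500)
    preferred_split_window_s: float = 0.300

    # synchronization
    frame_rate: float = 100.0
    pulse_interval_s: float = 3.0

    # statistics
    alpha: float = 0.05
    mad_factor: float = 3.0

    # session inclusion (more than 40 forelimb twitches required)
    min_forelimb_twitches: int = 41


_POSITIVE = {
    "bin_size_s", "z_threshold", "isolation_window_s", "wake_quiescence_s",
    "whisker_merge_gap_s", "pixel_change_threshold", "roi_threshold_mad_factor",
    "active_wake_window_s", "emg_z_threshold", "whh_smooth_bins",
    "wake_baseline_smooth_bins", "premove_wake_lookback_s",
    "premove_wake_extent_s", "kinematic_window_twitch_s",
    "kinematic_window_wake_s", "n_direction_bins", "selectivity_threshold",
    "calibration_px_per_mm", "frame_rate", "pulse_interval_s", "alpha",
    "mad_factor", "min_events", "min_forelimb_twitches",
    "preferred_split_window_s", "roi_min_bout_frames",
}
_UNIT_INTERVAL = {"atonia_quantile", "delta_quantile", "likelihood_flag_threshold"}
_WINDOWS = {
    "peth_window_s", "baseline_window_s", "twitch_class_window_s",
    "wake_class_window_s", "fano_window_twitch_s", "fano_window_wake_s",
    "premove_window_twitch_s", "premove_window_development_s",
    "activity_window_twitch_s", "activity_window_wake_s",
}


def validate_config(cfg: AnalysisConfig) -> AnalysisConfig:
    """Validate every field; raise ConfigError naming the key and bound."""
    for name in _POSITIVE:
        if getattr(cfg, name) <= 0:
            raise ConfigError(f"{name} must be > 0, got {getattr(cfg, name)!r}")
    for name in _UNIT_INTERVAL:
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
    for name in _WINDOWS:
        lo, hi = getattr(cfg, name)
        if not lo < hi:
            raise ConfigError(f"{name} must satisfy start < end, got {(lo, hi)!r}")
    if cfg.angle_mode not in ("at_peak", "path_mean"):
        raise ConfigError(
            f"angle_mode must be 'at_peak' or 'path_mean', got {cfg.angle_mode!r}"
        )
    w_lo, w_hi = cfg.peth_window_s
    span = w_hi - w_lo
    n = span / cfg.bin_size_s
    if abs(n - round(n)) > 1e-9:
        raise ConfigError(
            f"bin_size_s {cfg.bin_size_s} must divide peth_window_s span {span} evenly"
        )
    b_lo, b_hi = cfg.baseline_window_s
    if b_lo < w_lo or b_hi > w_hi:
        raise ConfigError("baseline_window_s must lie inside peth_window_s")
    return cfg


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    An absent or empty file yields the full default set. Keys may also be
    overridden programmatically with keyword arguments (applied after the
    file). Sequence values of length 2 are coerced to window tuples.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    data.update(overrides)

    valid_names = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - valid_names
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in _WINDOWS & set(data):
        v = data[key]
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise ConfigError(f"{key} must be a [start, end] pair, got {v!r}")
        data[key] = (float(v[0]), float(v[1]))
    cfg = AnalysisConfig(**data)
    return validate_config(cfg)


def config_to_dict(cfg: AnalysisConfig) -> dict:
    """JSON/YAML-serializable snapshot of a config (windows become lists)."""
    d = dataclasses.asdict(cfg)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
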