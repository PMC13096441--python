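"""End-to-end orchestration: simulate -> sync -> detect -> classify ->
metrics -> tuning -> stats.

Each stage writes its result tables under an output directory and the run
finishes with a JSON manifest (config snapshot, seed, file hashes, stage
outputs, package version) so identical manifests imply identical outputs.
Sessions failing the inclusion rule — more than 40 forelimb twitches and at
least one twitch-active neuron required — are excluded and logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .behavior import (
    classify_states,
    detect_movement_bouts,
    isolate_twitches,
    mark_wake_movement_onsets,
    merge_whisker_candidates,
)
from .config import AnalysisConfig, config_to_dict
from .errors import StageError
from .kinematics import (
    classify_selectivity,
    compute_kinematics,
    compute_tuning,
    spike_count_in_activity_window,
)
from .metrics import (
    baseline_rate_by_state,
    fano_factor,
    peak_latency,
    premove_proportion_twitch,
    premove_proportion_wake,
    width_at_half_height,
)
from .peth import build_peth, classify_neuron, zscore_peth
from .stats import StatsReport, t_test
from .sync import repair_frame_clock, validate_frame_intervals
from .synthetic import SessionData, SimulationParams, simulate_session
from .types import MovementEvent, sort_events

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(seed: int = 3, duration: float = 900.0) -> SessionData:
    """Small bundled-test session: 15 min, 4 neurons, twitches of 4 body parts.

    The roster covers a forelimb-tuned neuron, an untuned neuron, a
    direction+amplitude-tuned neuron and a wake-only neuron; regeneration
    with the same seed is byte-identical.
    """
    params = SimulationParams(session_duration=duration, seed=seed, twitch_rate=0.5)
    return simulate_session(params)


def session_passes_inclusion(
    session_events: list[MovementEvent],
    any_twitch_active: bool,
    config: AnalysisConfig,
) -> bool:
    """More than 40 forelimb twitches and >= 1 twitch-active neuron."""
    n_fore = sum(
        1 for e in session_events
        if e.body_part == "forelimb" and e.movement_class == "twitch"
    )
    return n_fore >= config.min_forelimb_twitches and any_twitch_active


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    seed: int = 0,
    sim_params: SimulationParams | None = None,
    session: SessionData | None = None,
) -> dict:
    """Run every stage on a (simulated) session and write all tables.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _write(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        outputs[name] = _sha256(path)
        return path

    if session is None:
        stage = "simulate"
        try:
            params = sim_params or SimulationParams(seed=seed)
            if params.seed != seed:
                params = dataclasses.replace(params, seed=seed)
            session = simulate_session(params)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {stage} failed: {exc}") from exc
        _write("spikes.csv", tio.write_spike_table, session.spike_trains)
        _write("scored_events.csv", tio.write_event_table, session.events)
        _write("timeline_true.csv", tio.write_state_timeline, session.timeline)
        _write("ground_truth.json", tio.write_ground_truth, session.ground_truth)

    try:
        stage = "sync"
        report = validate_frame_intervals(session.frame_clock)
        clock = repair_frame_clock(session.frame_clock)
        pd.DataFrame(
            [(r.gap_index, r.observed_frames, r.deficit) for r in report],
            columns=["gap_index", "observed_frames", "deficit"],
        ).to_csv(out / "sync_report.csv", index=False)
        outputs["sync_report.csv"] = _sha256(out / "sync_report.csv")
        _write("frames.csv", lambda c, p: tio.write_frame_clock(c, p, out / "pulses.csv"), clock)

        stage = "detect"
        candidates: list[MovementEvent] = []
        for part, series in session.pixel_series.items():
            if part == "whole_body":
                continue
            candidates.extend(detect_movement_bouts(series, body_part=part, config=config))
        candidates = merge_whisker_candidates(
            sort_events(candidates), config.whisker_merge_gap_s)
        wake_candidates = detect_movement_bouts(
            session.pixel_series["whole_body"], body_part="forelimb",
            movement_class="wake", config=config,
        )
        t_feat, tone, delta = session.state_features
        timeline = classify_states(
            t_feat, tone, delta, twitch_events=candidates,
            movement_events=wake_candidates, config=config,
        )
        _write("timeline_scored.csv", tio.write_state_timeline, timeline)
        twitches = [
            dataclasses.replace(e, state="REM")
            for e in candidates if timeline.state_at(e.onset) == "REM"
        ]
        wake_events = [
            dataclasses.replace(e, state=timeline.state_at(e.onset))
            for e in mark_wake_movement_onsets(wake_candidates, config.wake_quiescence_s)
            if (timeline.state_at(e.onset) or "").endswith("wake")
        ]
        detected = sort_events(twitches + wake_events)
        _write("detected_events.csv", tio.write_event_table, detected)

        stage = "classify"
        isolated = isolate_twitches(twitches, config.isolation_window_s, "cross_bodypart")
        by_part = {
            part: [e for e in isolated if e.body_part == part]
            for part in {e.body_part for e in isolated}
        }
        classifications = [
            classify_neuron(train, by_part, wake_events, config)
            for train in session.spike_trains
        ]
        cls_df = pd.DataFrame([
            {
                "neuron_id": c.neuron_id,
                "region": train.region_label,
                "twitch_active": c.twitch_active,
                "wake_active": c.wake_active,
                "preferred_body_part": c.preferred_body_part or "",
                **{f"peak_z_{k}": v for k, v in c.peak_z_by_body_part.items()},
            }
            for c, train in zip(classifications, session.spike_trains)
        ])
        cls_df.to_csv(out / "classification.csv", index=False)
        outputs["classification.csv"] = _sha256(out / "classification.csv")

        if not session_passes_inclusion(
            twitches, any(c.twitch_active for c in classifications), config
        ):
            logger.warning("session excluded: inclusion rule not met")
            manifest = _manifest(config, seed, outputs, excluded=True)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            return manifest

        stage = "metrics"
        rows = []
        fore = by_part.get("forelimb", [])
        for train, c in zip(session.spike_trains, classifications):
            row: dict = {"neuron_id": train.neuron_id, "region": train.region_label}
            rates = baseline_rate_by_state(train, timeline)
            for state, rate in rates.items():
                row[f"rate_{state}"] = rate
            if c.twitch_active and fore:
                p = zscore_peth(build_peth(
                    train, fore, config.peth_window_s, config.bin_size_s,
                    config.baseline_window_s,
                ))
                row["peak_latency_ms"] = peak_latency(p, config.twitch_class_window_s)
                row["whh_ms"] = width_at_half_height(p, config)
                row["premove_twitch"] = premove_proportion_twitch(
                    p, config.premove_window_twitch_s)
                row["fano_twitch"] = fano_factor(train, fore, config.fano_window_twitch_s)
            if c.wake_active and wake_events:
                p = zscore_peth(build_peth(
                    train, wake_events, config.peth_window_s, config.bin_size_s,
                    config.baseline_window_s,
                ))
                row["premove_wake"] = premove_proportion_wake(p, config)
                row["fano_wake"] = fano_factor(train, wake_events, config.fano_window_wake_s)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        outputs["metrics.csv"] = _sha256(out / "metrics.csv")

        stage = "tuning"
        kin_rows, tuning_rows = [], []
        usable = []
        for ev in wake_events:
            try:
                kin = compute_kinematics(session.trajectory, ev.onset, "wake", config)
            except Exception:  # trajectory gap
                continue
            if kin.angle_deg is None:
                continue
            usable.append((ev, kin))
            kin_rows.append({
                "onset_s": ev.onset, "class": "wake",
                "amplitude_mm": kin.amplitude_mm, "angle_deg": kin.angle_deg,
            })
        pd.DataFrame(kin_rows).to_csv(out / "kinematics.csv", index=False)
        outputs["kinematics.csv"] = _sha256(out / "kinematics.csv")
        for train in session.spike_trains:
            if len(usable) < 3:
                continue
            counts = np.array([
                spike_count_in_activity_window(train, ev, "wake", config)
                for ev, _ in usable
            ])
            tun = compute_tuning(
                train.neuron_id,
                np.array([k.angle_deg for _, k in usable]),
                np.array([k.amplitude_mm for _, k in usable]),
                counts, config,
            )
            tuning_rows.append({
                "neuron_id": train.neuron_id,
                "eta_sq": tun.eta_sq_direction, "r_sq": tun.r_sq_amplitude,
                "selectivity": classify_selectivity(tun),
                "n_movements": tun.n_movements,
            })
        pd.DataFrame(tuning_rows).to_csv(out / "tuning.csv", index=False)
        outputs["tuning.csv"] = _sha256(out / "tuning.csv")

        stage = "stats"
        report = StatsReport(alpha=config.alpha)
        mdf = pd.DataFrame(rows)
        regions = sorted({r for r in mdf.get("region", pd.Series(dtype=str)) if r})
        if len(regions) == 2 and "rate_REM" in mdf.columns and "rate_quiet_wake" in mdf.columns:
            sub = mdf.dropna(subset=["rate_REM", "rate_quiet_wake"])
            if len(sub) >= 2:
                report.results.append(t_test(
                    sub["rate_REM"], sub["rate_quiet_wake"],
                    contrast="REM_vs_wake_rate", paired=True,
                ))
        report.to_frame().to_csv(out / "stats.csv", index=False)
        outputs["stats.csv"] = _sha256(out / "stats.csv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage} failed: {exc}") from exc

    manifest = _manifest(config, seed, outputs, excluded=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _manifest(config: AnalysisConfig, seed: int, outputs: dict, excluded: bool) -> dict:
    return {
        "tool": "twitchlab",
        "version": __version__,
        "seed": seed,
        "config": config_to_dict(config),
        "outputs": dict(sorted(outputs.items())),
        "session_excluded": excluded,
    }
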