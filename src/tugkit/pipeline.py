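"""End-to-end orchestration: radar + insole streams to a full TUG report.

The full analysis of one trial runs: radar segmentation (T0..T5 and the
five activities), insole stride detection with force validation, per-stride
length estimation by the three acceleration approaches plus the radar
displacement, gait parameters, the ROFA score against a baseline, and the
paired insole-vs-radar stride-length comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .config import PipelineConfig, load_config
from .insole import (
    InsoleRecording,
    compute_gait_parameters,
    detect_stride_peaks,
    detect_sts_phases,
    locking_period,
    lowpass_ay,
    normalize_recording,
    validate_with_force,
)
from .radar import RadarTrace, radar_stride_metrics, segment_tug
from .rofa import BaselineStats, score_trial
from .stats import compare_paired
from .stride_length import StrideWindow, estimate_all

__all__ = ["run_trial", "run_pipeline", "trial_parameters"]

log = logging.getLogger("tugkit")

APPROACHES = ("mean_abs", "weinberg", "scarlett")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "kf": {
                "ts": config.kf.sample_interval_s,
                "r": config.kf.measurement_noise,
                "q0": np.diag(config.kf.process_noise).tolist(),
            },
            "seg": asdict(config.segmentation),
            "insole": asdict(config.insole),
            "cal": {"k1": config.calibration.k1, "k": config.calibration.k},
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stride_windows(
    norm_time: np.ndarray, ay_raw: np.ndarray, boundaries: list[tuple[float, float]]
) -> list[StrideWindow]:
    out = []
    for start, end in boundaries:
        sel = (norm_time >= start) & (norm_time < end)
        out.append(StrideWindow(ay_raw[sel]))
    return out


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def run_trial(
    radar: RadarTrace,
    insole: InsoleRecording,
    config: PipelineConfig | None = None,
    baseline: BaselineStats | None = None,
    force_subset: tuple[int, ...] | None = None,
    approach: str = "weinberg",
) -> dict:
    """Analyse one paired trial and return the full report dictionary."""
    config = config or PipelineConfig()
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}")
    chash = _config_hash(config)

    log.info("stage=segment_radar n=%d config=%s", len(radar), chash)
    events = segment_tug(radar, config.segmentation, config.kf)

    log.info("stage=segment_insole n=%d config=%s", len(insole), chash)
    norm = normalize_recording(insole, force_subset)
    ay_filtered = lowpass_ay(norm.ay, norm.sample_rate_hz, config.insole)
    _, lockp = locking_period(ay_filtered, norm.sample_rate_hz)
    strides = detect_stride_peaks(
        ay_filtered, norm.sample_rate_hz, lockp, config.insole
    )
    validation = validate_with_force(
        norm.total_force, strides, norm.sample_rate_hz, config.insole
    )
    try:
        s2st_force, st2s_force = detect_sts_phases(
            norm.total_force, norm.sample_rate_hz
        )
        force_phases = {"sit_to_stand": list(s2st_force), "stand_to_sit": list(st2s_force)}
    except ValueError as err:
        force_phases = {"error": str(err)}

    boundaries = strides.stride_boundaries
    t_lo, t_hi = radar.time[0], radar.time[-1]
    boundaries = [(a, b) for a, b in boundaries if a >= t_lo and b <= t_hi]

    log.info("stage=stride_length n_strides=%d config=%s", len(boundaries), chash)
    windows = _stride_windows(norm.time, norm.ay_raw, boundaries)
    estimates = {name: [] for name in APPROACHES}
    for w in windows:
        for name, value in estimate_all(w, config.calibration).items():
            estimates[name].append(value)
    estimates = {k: np.asarray(v) for k, v in estimates.items()}
    radar_metrics = radar_stride_metrics(radar, boundaries)

    turn_iv = (events.t2, events.t3)
    overlaps = [_overlap(b, turn_iv) for b in boundaries]
    turn_idx = int(np.argmax(overlaps)) if overlaps and max(overlaps) > 0 else None
    labels = [
        "turn" if i == turn_idx else "walk" for i in range(len(boundaries))
    ]

    gait = compute_gait_parameters(strides, estimates[approach][: len(boundaries)]) \
        if boundaries else None

    report: dict = {
        "config_hash": chash,
        "events": events.to_dict(),
        "n_strides": len(boundaries),
        "locking_period_s": lockp,
        "stride_boundaries": [[float(a), float(b)] for a, b in boundaries],
        "stride_labels": labels,
        "force_validation": asdict(validation),
        "force_phases": force_phases,
        "stride_length_m": {k: v.tolist() for k, v in estimates.items()},
        "radar_stride_length_m": radar_metrics.lengths.tolist(),
        "radar_stride_speed_mps": radar_metrics.speeds.tolist(),
        "approach": approach,
    }
    if gait is not None:
        report["gait_parameters"] = {
            "stride_time_s": gait.stride_time_s.tolist(),
            "cadence_steps_min": gait.cadence_steps_min.tolist(),
            "stride_length_m": gait.stride_length_m.tolist(),
            "stride_speed_mps": gait.stride_speed_mps.tolist(),
        }

    if len(boundaries) >= 2:
        log.info("stage=compare n_pairs=%d config=%s", len(boundaries), chash)
        cmp_result = compare_paired(estimates[approach], radar_metrics.lengths)
        report["comparison"] = {
            "statistic": cmp_result.statistic,
            "p_value": cmp_result.p_value,
            "n_pairs": cmp_result.n_pairs,
            "rmse_m": cmp_result.rmse,
            "method": cmp_result.method,
            "significant_at_0.05": cmp_result.significant,
        }

    if baseline is not None and gait is not None:
        log.info("stage=rofa config=%s", chash)
        rofa = score_trial(
            {
                "stride_length_m": gait.stride_length_m,
                "stride_time_s": gait.stride_time_s,
                "cadence_steps_min": gait.cadence_steps_min,
                "stride_speed_mps": gait.stride_speed_mps,
            },
            baseline,
        )
        report["rofa"] = rofa.to_dict()

    return report


def trial_parameters(
    radar: RadarTrace,
    insole: InsoleRecording,
    config: PipelineConfig | None = None,
    force_subset: tuple[int, ...] | None = None,
    approach: str = "weinberg",
) -> dict[str, np.ndarray]:
    """Per-stride gait-parameter table of one trial (for baseline building)."""
    report = run_trial(
        radar, insole, config=config, force_subset=force_subset, approach=approach
    )
    gp = report.get("gait_parameters")
    if gp is None:
        raise ValueError("trial yielded no strides")
    return {k: np.asarray(v) for k, v in gp.items()}


def run_pipeline(
    radar_csv: str | Path,
    insole_csv: str | Path,
    config: str | Path | dict | None = None,
    baseline: str | Path | None = None,
    force_subset: tuple[int, ...] | None = None,
    approach: str = "weinberg",
) -> dict:
    """File-based entry point: read the two streams, analyse, return report."""
    from .io import read_baseline_json, read_insole_csv, read_radar_csv

    try:
        radar = read_radar_csv(radar_csv)
    except (OSError, ValueError) as err:
        raise RuntimeError(f"stage=read_radar: {err}") from err
    try:
        insole = read_insole_csv(insole_csv)
    except (OSError, ValueError) as err:
        raise RuntimeError(f"stage=read_insole: {err}") from err
    cfg = load_config(config)
    base = read_baseline_json(baseline) if baseline is not None else None
    return run_trial(
        radar, insole, config=cfg, baseline=base,
        force_subset=force_subset, approach=approach,
    )
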