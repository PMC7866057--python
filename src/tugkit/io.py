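"""CSV/JSON readers and writers for radar traces, insole recordings,
segmentation events, baselines and ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .insole import InsoleRecording
from .radar import RadarTrace, TUGEvents
from .rofa import BaselineStats
from .simulate import GroundTruth

__all__ = [
    "read_radar_csv",
    "write_radar_csv",
    "read_insole_csv",
    "write_insole_csv",
    "write_events_json",
    "read_events_json",
    "write_baseline_json",
    "read_baseline_json",
    "write_truth_json",
]


def read_radar_csv(path: str | Path) -> RadarTrace:
    """Radar CSV with header ``time_s,distance_m``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_s", "distance_m"} - set(df.columns)
    if missing:
        raise ValueError(f"radar CSV missing columns: {sorted(missing)}")
    return RadarTrace(df["time_s"].to_numpy(float), df["distance_m"].to_numpy(float))


def write_radar_csv(trace: RadarTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "distance_m": trace.distance}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_insole_csv(path: str | Path) -> InsoleRecording:
    """Insole CSV with header ``time_s,ay,fsr1,fsr2[,fsr3[,fsr4]]``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns or "ay" not in df.columns:
        raise ValueError("insole CSV must have time_s and ay columns")
    fsr_cols = [c for c in df.columns if c.startswith("fsr")]
    if not 2 <= len(fsr_cols) <= 4:
        raise ValueError("insole CSV must have 2-4 fsr columns")
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return InsoleRecording(
        time=t,
        ay=df["ay"].to_numpy(float),
        forces=df[sorted(fsr_cols)].to_numpy(float),
        sample_rate_hz=fs,
    )


def write_insole_csv(rec: InsoleRecording, path: str | Path) -> None:
    data = {"time_s": rec.time, "ay": rec.ay}
    for i in range(rec.n_channels):
        data[f"fsr{i + 1}"] = rec.forces[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_events_json(events: TUGEvents, path: str | Path) -> None:
    Path(path).write_text(json.dumps(events.to_dict(), indent=2))


def read_events_json(path: str | Path) -> TUGEvents:
    d = json.loads(Path(path).read_text())
    return TUGEvents(*(float(d[f"t{i}"]) for i in range(6)))


def write_baseline_json(baseline: BaselineStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(baseline.to_dict(), indent=2))


def read_baseline_json(path: str | Path) -> BaselineStats:
    return BaselineStats.from_dict(json.loads(Path(path).read_text()))


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))
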