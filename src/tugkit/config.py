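"""JSON configuration loading.

A single JSON file can configure every stage.  Keys are grouped per stage
(nested objects); dotted flat keys like ``"kf.ts_s"`` are also accepted::

    {
      "kf": {"ts_s": 0.2, "r": 0.04, "q0_diag": [0.04, 0.01, 0.01]},
      "segmentation": {"radar_offset_m": 0.5, "walk_distance_m": 3.0,
                        "standing_offset_m": 0.3, "velocity_threshold_mps": 0.4},
      "insole": {"median_window": 5, "butterworth_cutoff_hz": 6.0,
                  "max_stride_time_s": 2.5},
      "calibration": {"k1": 0.98, "k": 0.9763}
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .insole import PreprocessConfig
from .kalman import FilterConfig
from .radar import SegmentationConfig
from .stride_length import CalibrationConstants

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    kf: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    insole: PreprocessConfig = field(default_factory=PreprocessConfig)
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)


def _nest(flat: dict) -> dict:
    """Expand dotted keys into nested dictionaries."""
    out: dict = {}
    for key, value in flat.items():
        parts = key.split(".")
        node = out
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        if isinstance(value, dict):
            node.setdefault(parts[-1], {}).update(_nest(value))
        else:
            node[parts[-1]] = value
    return out


_KF_KEYS = {"ts_s": "sample_interval_s", "r": "measurement_noise"}


def _build_kf(section: dict) -> FilterConfig:
    kwargs = {}
    for key, value in section.items():
        if key == "q0_diag":
            kwargs["process_noise"] = np.diag(np.asarray(value, dtype=float))
        else:
            kwargs[_KF_KEYS.get(key, key)] = value
    return FilterConfig(**kwargs)


def load_config(source: str | Path | dict | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a JSON file path or dict."""
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        raw = json.loads(Path(source).read_text())
    else:
        raw = source
    nested = _nest(raw)
    return PipelineConfig(
        kf=_build_kf(nested.get("kf", {})),
        segmentation=SegmentationConfig(**nested.get("segmentation", {})),
        insole=PreprocessConfig(**nested.get("insole", {})),
        calibration=CalibrationConstants(**nested.get("calibration", {})),
    )
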