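"""Risk-of-falling (ROFA) scoring from gait-parameter deviations.

Each gait parameter k (stride length, stride time, cadence, stride speed)
is compared against a personal or control-group baseline (mean GkM, SD
sigma_k).  The deviation ratio

    Rk = |(Gk - GkM) / sigma_k|

is turned into a 0-100 gait-deviation score Sk = 100 - 10 Rk (clamped at
0), so a score of 100 means gait at baseline and every 10 points lost is
one baseline standard deviation of deviation.  Parameter scores are
combined with convex weights (equal by default) into the composite TUG
score, interpreted in five bands: [0,25) very high risk, [25,50) high,
[50,75) medium, [75,100) low, and exactly 100 very low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BaselineStats",
    "ROFAResult",
    "RISK_BANDS",
    "compute_ratio",
    "compute_sk",
    "compute_tug_score",
    "classify_risk",
    "build_baseline",
    "score_trial",
]

RISK_BANDS = ("very high", "high", "medium", "low", "very low")

DEFAULT_PARAMETERS = (
    "stride_length_m",
    "stride_time_s",
    "cadence_steps_min",
    "stride_speed_mps",
)


@dataclass(frozen=True)
class BaselineEntry:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("baseline SD must be > 0")


@dataclass
class BaselineStats:
    """Per-parameter baseline mean and SD, with provenance."""

    parameters: dict[str, BaselineEntry]
    provenance: str = "self-baseline"

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "parameters": {
                k: {"mean": v.mean, "sd": v.sd} for k, v in self.parameters.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineStats":
        return cls(
            parameters={
                k: BaselineEntry(float(v["mean"]), float(v["sd"]))
                for k, v in d["parameters"].items()
            },
            provenance=d.get("provenance", "self-baseline"),
        )


@dataclass
class ROFAResult:
    """Per-parameter scores and the composite 0-100 TUG score."""

    parameter_scores: dict[str, float]   # mean Sk per parameter
    parameter_ratios: dict[str, float]   # mean Rk per parameter
    weights: dict[str, float]
    tug_score: float
    risk_band: str

    def to_dict(self) -> dict:
        return {
            "parameter_scores": self.parameter_scores,
            "parameter_ratios": self.parameter_ratios,
            "weights": self.weights,
            "tug_score": self.tug_score,
            "risk_band": self.risk_band,
        }


def compute_ratio(gk: float, baseline: BaselineEntry) -> float:
    """Deviation ratio Rk: how many baseline SDs the value is from its mean."""
    return abs((gk - baseline.mean) / baseline.sd)


def compute_sk(rk: float) -> float:
    """Gait-deviation score Sk = 100 - 10 Rk, clamped to [0, 100]."""
    if rk < 0:
        raise ValueError("deviation ratio must be >= 0")
    return float(np.clip(100.0 - 10.0 * rk, 0.0, 100.0))


def compute_tug_score(
    sk_values: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Convex combination of per-parameter scores (equal weights default)."""
    sk = np.asarray(sk_values, dtype=float)
    if sk.size == 0:
        raise ValueError("no parameter scores to combine")
    if weights is None:
        w = np.full(sk.size, 1.0 / sk.size)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != sk.shape or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return float(np.dot(w, sk))


def classify_risk(score: float) -> str:
    """Risk band for a composite score in [0, 100]."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("score outside [0, 100]")
    if score == 100.0:
        return "very low"
    return RISK_BANDS[int(score // 25)]


def build_baseline(
    trials: list[dict[str, np.ndarray]], provenance: str = "self-baseline"
) -> BaselineStats:
    """Pooled per-parameter baseline over all strides of all baseline trials.

    Each trial maps parameter name -> per-stride values.  Mean and sample SD
    (ddof=1) are pooled across strides of every trial.  Parameters with zero
    pooled variance are flagged with a warning and excluded from scoring.
    """
    if not trials:
        raise ValueError("need at least one baseline trial")
    names: list[str] = []
    for tr in trials:
        for k in tr:
            if k not in names:
                names.append(k)
    params: dict[str, BaselineEntry] = {}
    for k in names:
        pooled = np.concatenate(
            [np.atleast_1d(np.asarray(tr[k], dtype=float)) for tr in trials if k in tr]
        )
        if pooled.size < 2:
            raise ValueError(f"parameter {k!r}: need at least 2 pooled strides")
        sd = float(np.std(pooled, ddof=1))
        if sd == 0:
            warnings.warn(
                f"parameter {k!r} has zero pooled variance; excluded from scoring",
                stacklevel=2,
            )
            continue
        params[k] = BaselineEntry(mean=float(np.mean(pooled)), sd=sd)
    return BaselineStats(parameters=params, provenance=provenance)


def score_trial(
    trial: dict[str, np.ndarray],
    baseline: BaselineStats,
    weights: dict[str, float] | None = None,
    per_stride: bool = True,
) -> ROFAResult:
    """Score one trial against a baseline.

    With ``per_stride=True`` (default) each stride receives its own
    deviation score per parameter and the stride scores are averaged before
    weighting across parameters; otherwise the trial-mean parameter value is
    scored directly.
    """
    common = [k for k in trial if k in baseline.parameters]
    if not common:
        raise ValueError("no overlap between trial parameters and baseline")
    scores: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for k in common:
        vals = np.atleast_1d(np.asarray(trial[k], dtype=float))
        entry = baseline.parameters[k]
        if per_stride:
            rk = np.array([compute_ratio(v, entry) for v in vals])
            sk = np.array([compute_sk(r) for r in rk])
            scores[k] = float(sk.mean())
            ratios[k] = float(rk.mean())
        else:
            ratios[k] = compute_ratio(float(vals.mean()), entry)
            scores[k] = compute_sk(ratios[k])
    if weights is None:
        w = {k: 1.0 / len(common) for k in common}
    else:
        missing = [k for k in common if k not in weights]
        if missing:
            raise ValueError(f"weights missing for parameters {missing}")
        w = {k: float(weights[k]) for k in common}
    tug = compute_tug_score(
        np.array([scores[k] for k in common]), np.array([w[k] for k in common])
    )
    return ROFAResult(
        parameter_scores=scores,
        parameter_ratios=ratios,
        weights=w,
        tug_score=tug,
        risk_band=classify_risk(tug),
    )
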