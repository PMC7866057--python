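"""TUG activity segmentation from a radar range trace.

The radar is placed a distance ``D_pos`` behind the chair and reports the
range D to the subject.  A complete Timed Up and Go trial appears in the
range trace as: a quasi-static sit plateau, a small rise of ``d_qs`` while
standing up, a ramp out to ``D_pos + 3 m``, a plateau while turning 180
degrees, a mirrored ramp back, and a final descent while sitting down.
Segmentation finds the six transition points T0..T5 bounding the five
activities (sit-to-stand, walk forward, turn, walk back, stand-to-sit):

* onset: first time the Kalman-filtered velocity magnitude reaches
  ``V_thres`` (0.4 m/s); if it never does within the quasi-static timeout
  the trace is declared quasi-static and no events are produced.
* T0: first point in the 3 s look-back from onset where D > D_pos,
* T1: first point >= T0 where D >= D_pos + d_qs,
* T2: first point where D >= D_pos + walk_distance,
* T3: last point of the contiguous run with D >= D_pos + walk_distance - eps
  (eps = one 0.1 m range cell),
* T4: first point after T3 where D <= D_pos + d_qs,
* T5: first point after T4 where D <= D_pos (the mirror of the T0 rule).

All range thresholds are evaluated on the measured range with a
majority-vote debounce (a single-sample noise spike can never trigger a
transition); the Kalman filter is used for velocity only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .kalman import FilterConfig, estimate_kinematics

__all__ = [
    "RadarTrace",
    "SegmentationConfig",
    "TUGEvents",
    "RadarStrideMetrics",
    "QuasiStaticError",
    "IncompleteTrialError",
    "detect_walk_onset",
    "segment_tug",
    "radar_stride_metrics",
    "resample_trace",
]

PHASE_LABELS = ("sit_to_stand", "walk_forward", "turn", "walk_back", "stand_to_sit")


class QuasiStaticError(ValueError):
    """The trace never shows walking-level velocity: no TUG activity."""


class IncompleteTrialError(ValueError):
    """The trace never reaches the far end of the walkway."""


@dataclass(frozen=True)
class RadarTrace:
    """Uniformly sampled range-to-subject series.

    time : seconds, strictly increasing, uniform within 1e-3 relative
    distance : meters, >= 0
    """

    time: np.ndarray
    distance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.distance, dtype=float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("time and distance must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.abs(dt - dt.mean()) > 1e-3 * dt.mean() + 1e-9):
            raise ValueError("non-uniform sampling beyond tolerance")
        if np.any(d < 0):
            raise ValueError("distance must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "distance", d)

    @property
    def sample_interval_s(self) -> float:
        return float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class SegmentationConfig:
    """Geometry and thresholds of the TUG layout and segmenter."""

    radar_offset_m: float = 0.5        # D_pos: radar-to-chair distance
    walk_distance_m: float = 3.0       # length of the walkway
    standing_offset_m: float = 0.3     # d_qs: chair-to-standing-position
    velocity_threshold_mps: float = 0.4  # V_thres: walking onset
    onset_window_s: float = 3.0        # accumulation window / look-back
    quasi_static_timeout_s: float = 30.0  # X_secs
    range_resolution_m: float = 0.1    # eps for the turn-plateau run
    persistence_samples: int = 2       # debounce on range-threshold crossings

    def __post_init__(self) -> None:
        for name in (
            "radar_offset_m",
            "walk_distance_m",
            "standing_offset_m",
            "velocity_threshold_mps",
            "onset_window_s",
            "quasi_static_timeout_s",
            "range_resolution_m",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.walk_distance_m > self.standing_offset_m:
            raise ValueError("walk_distance_m must exceed standing_offset_m")
        if self.persistence_samples < 1:
            raise ValueError("persistence_samples must be >= 1")


@dataclass(frozen=True)
class TUGEvents:
    """Transition points T0..T5 (s) and the five labeled activity phases."""

    t0: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float

    def __post_init__(self) -> None:
        ts = self.times
        if not np.all(np.diff(ts) > 0):
            raise ValueError("transition points must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([self.t0, self.t1, self.t2, self.t3, self.t4, self.t5])

    @property
    def phases(self) -> list[dict]:
        ts = self.times
        return [
            {"label": lab, "start_s": float(ts[i]), "end_s": float(ts[i + 1])}
            for i, lab in enumerate(PHASE_LABELS)
        ]

    def to_dict(self) -> dict:
        d = {f"t{i}": float(t) for i, t in enumerate(self.times)}
        d["phases"] = self.phases
        return d


@dataclass(frozen=True)
class RadarStrideMetrics:
    """Per-stride length (m) and speed (m/s) from radar displacement."""

    lengths: np.ndarray
    speeds: np.ndarray


def _filter_config(trace: RadarTrace) -> FilterConfig:
    return FilterConfig(sample_interval_s=trace.sample_interval_s)


def _sustained(mask: np.ndarray, n: int) -> np.ndarray:
    """Debounced crossing indices: sample i holds and so do at least n-1 of
    the next n samples (majority vote).  A single-sample spike can never
    qualify, yet an isolated dropout inside a genuine crossing does not
    postpone detection the way a strict consecutive-run test would.
    On noise-free step-like masks this reduces to the first index of a run.
    """
    if n <= 1:
        return np.flatnonzero(mask)
    following = np.zeros(mask.size, dtype=int)
    for k in range(1, n + 1):
        shifted = np.zeros_like(mask)
        shifted[:-k] = mask[k:]
        following += shifted
    return np.flatnonzero(mask & (following >= n - 1))


def detect_walk_onset(
    trace: RadarTrace,
    config: SegmentationConfig | None = None,
    kf_config: FilterConfig | None = None,
) -> float | None:
    """Time of walking onset, or None for a quasi-static trace.

    The filter accumulates at least ``onset_window_s`` of data before a
    verdict; the onset is the first time the filtered |velocity| reaches
    ``velocity_threshold_mps``.  If that never happens within
    ``quasi_static_timeout_s`` the trace is quasi-static.
    """
    config = config or SegmentationConfig()
    if trace.time[-1] - trace.time[0] < config.onset_window_s:
        raise ValueError("trace shorter than the onset window")
    kf = kf_config or _filter_config(trace)
    vel = estimate_kinematics(trace.distance, kf)[:, 1]
    hit = np.flatnonzero(np.abs(vel) >= config.velocity_threshold_mps)
    if hit.size == 0:
        return None
    onset = float(trace.time[hit[0]])
    if onset - trace.time[0] > config.quasi_static_timeout_s:
        return None
    return onset


def segment_tug(
    trace: RadarTrace,
    config: SegmentationConfig | None = None,
    kf_config: FilterConfig | None = None,
) -> TUGEvents:
    """Segment a full TUG trial into its six transition points."""
    config = config or SegmentationConfig()
    onset = detect_walk_onset(trace, config, kf_config)
    if onset is None:
        raise QuasiStaticError("no activity: trace is quasi-static")

    t = trace.time
    d = trace.distance
    n_persist = config.persistence_samples
    d_pos = config.radar_offset_m
    far = d_pos + config.walk_distance_m
    stand = d_pos + config.standing_offset_m

    if d.max() < far - 0.5 * config.range_resolution_m:
        raise IncompleteTrialError(
            f"incomplete trial: range never reaches {far:.2f} m"
        )

    onset_idx = int(np.searchsorted(t, onset))
    lookback_idx = int(np.searchsorted(t, onset - config.onset_window_s))

    # At T2 and T4 the subject reaches the threshold range and hovers at it
    # (turn plateau, pause at the chair), so "becomes equal to" is tested
    # with half a range cell of slack; T0/T1/T5 are transversal crossings
    # and stay exact.
    margin = 0.5 * config.range_resolution_m

    # T0: first debounced point with D > D_pos inside the look-back window.
    above = d > d_pos
    cand = _sustained(above, n_persist)
    cand = cand[(cand >= lookback_idx) & (cand <= onset_idx)]
    if cand.size == 0:
        # fall back to the first debounced crossing anywhere before onset
        cand = _sustained(above, n_persist)
        cand = cand[cand <= onset_idx]
        if cand.size == 0:
            raise QuasiStaticError("no sit-to-stand rise found before onset")
    i0 = int(cand[0])

    # T1: first point >= T0 with D >= D_pos + d_qs.
    cand = _sustained(d >= stand, n_persist)
    cand = cand[cand >= i0]
    if cand.size == 0:
        raise IncompleteTrialError("range never reaches the standing offset")
    i1 = int(cand[0])

    # T2: first point with D >= D_pos + walk_distance.
    cand = _sustained(d >= far - margin, n_persist)
    cand = cand[cand >= i1]
    if cand.size == 0:
        raise IncompleteTrialError("range never reaches the walkway end")
    i2 = int(cand[0])

    # T3: end of the contiguous turn plateau, tolerating single-sample
    # dropouts below far - eps (the debounce mirrored).
    near_far = d >= far - config.range_resolution_m
    i3 = i2
    j = i2
    while j + 1 < d.size:
        if near_far[j + 1]:
            j += 1
            i3 = j
        elif j + 2 < d.size and near_far[j + 2] and n_persist > 1:
            j += 2
            i3 = j
        else:
            break

    # T4: first debounced point after T3 with D <= D_pos + d_qs.
    cand = _sustained(d <= stand + margin, n_persist)
    cand = cand[cand > i3]
    if cand.size == 0:
        raise IncompleteTrialError("walk back never returns to the chair area")
    i4 = int(cand[0])

    # T5: first debounced point after T4 with D <= D_pos (mirror of T0).
    cand = _sustained(d <= d_pos, n_persist)
    cand = cand[cand > i4]
    if cand.size == 0:
        raise IncompleteTrialError("stand-to-sit never completes")
    i5 = int(cand[0])

    return TUGEvents(*(float(t[i]) for i in (i0, i1, i2, i3, i4, i5)))


def radar_stride_metrics(
    trace: RadarTrace, stride_intervals: list[tuple[float, float]]
) -> RadarStrideMetrics:
    """Per-stride length and speed from radar range displacement.

    Stride length is the absolute range displacement over the stride interval
    (sign-free, so walk-back strides count positively); stride speed is
    length over duration.  Range at the interval endpoints is interpolated
    linearly between samples.
    """
    lengths = []
    speeds = []
    t0, t1 = trace.time[0], trace.time[-1]
    for start, end in stride_intervals:
        if not (end > start):
            raise ValueError("stride interval must have positive duration")
        if start < t0 - 1e-9 or end > t1 + 1e-9:
            raise ValueError("stride interval outside trace span")
        d_start = float(np.interp(start, trace.time, trace.distance))
        d_end = float(np.interp(end, trace.time, trace.distance))
        sl = abs(d_end - d_start)
        lengths.append(sl)
        speeds.append(sl / (end - start))
    return RadarStrideMetrics(np.asarray(lengths), np.asarray(speeds))


def resample_trace(trace: RadarTrace, target_times: np.ndarray) -> RadarTrace:
    """Cubic resampling of the range trace onto new time stamps.

    Used to put the radar (a few Hz) and the insole (~100 Hz) on a common
    clock.  Transition points are always located on the original trace;
    resampling is for joint plotting/stride mapping only.  Extrapolation is
    refused.
    """
    tt = np.asarray(target_times, dtype=float)
    if tt.min() < trace.time[0] - 1e-12 or tt.max() > trace.time[-1] + 1e-12:
        raise ValueError("target times outside the source span (no extrapolation)")
    spline = CubicSpline(trace.time, trace.distance)
    return RadarTrace(tt, np.maximum(spline(tt), 0.0))
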