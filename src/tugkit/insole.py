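"""Stride and phase detection from an instrumented insole.

The insole carries a 3-axis accelerometer (only the anteroposterior y-axis
is used: it carries the walking signature) and 2-4 force-sensitive resistors
(FSR) under the heel and metatarsal pads.  Stride detection follows the
zero-crossing / locking-period scheme: the filtered acceleration crosses
zero twice per step, the mean inter-crossing interval sets a locking period
lockP, candidate peaks are screened by the amplitude drops to their
flanking minima (PL to the toe-off minimum before, PR to the heel-strike
minimum after) and by the admissible inter-peak gap lockP <= gap <= Max_time.
The number of strides is the number of valid peaks minus one.  The total
FSR force validates the count (one stance/swing cycle per stride) and
locates sit-to-stand / stand-to-sit through its loading/unloading ramps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, medfilt

__all__ = [
    "InsoleRecording",
    "NormalizedRecording",
    "PreprocessConfig",
    "StrideEvents",
    "GaitParameters",
    "ForceValidation",
    "normalize_recording",
    "lowpass_ay",
    "locking_period",
    "detect_stride_peaks",
    "validate_with_force",
    "detect_sts_phases",
    "compute_gait_parameters",
]


@dataclass(frozen=True)
class InsoleRecording:
    """Timestamped y-acceleration and FSR force channels.

    time : seconds, strictly increasing
    ay : anteroposterior acceleration (sensor units / g)
    forces : (n_samples, n_channels) with 2-4 channels
    sample_rate_hz : nominal sampling rate
    """

    time: np.ndarray
    ay: np.ndarray
    forces: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        ay = np.asarray(self.ay, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        if f.ndim == 1:
            f = f[:, None]
        if t.ndim != 1 or ay.shape != t.shape or f.shape[0] != t.size:
            raise ValueError("time, ay and forces must share the sample axis")
        if not 2 <= f.shape[1] <= 4:
            raise ValueError("expected between 2 and 4 force channels")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "ay", ay)
        object.__setattr__(self, "forces", f)

    @property
    def n_channels(self) -> int:
        return self.forces.shape[1]

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class NormalizedRecording:
    """Normalized view of a recording: z-scored Ay plus unit-max total force.

    ``ay_raw`` keeps the unnormalized acceleration: the stride-length
    estimators need physical amplitudes, while segmentation runs on the
    z-scored copy.
    """

    time: np.ndarray
    ay: np.ndarray          # z-scored (population SD)
    ay_raw: np.ndarray
    total_force: np.ndarray  # sum over the selected channels, max exactly 1
    sample_rate_hz: float
    force_subset: tuple[int, ...]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering and peak-admissibility settings."""

    median_window: int = 5
    butterworth_order: int = 4
    butterworth_cutoff_hz: float = 6.0
    max_stride_time_s: float = 2.5       # Max_time: longest admissible gap
    shape_similarity_frac: float = 0.35  # min flank drop vs the best peak
    peak_threshold_frac: float | None = None  # optional absolute gate, off
    force_high_level: float = 0.6
    force_low_level: float = 0.2

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if not 0 < self.shape_similarity_frac < 1:
            raise ValueError("shape_similarity_frac must be in (0, 1)")
        if not self.force_low_level < self.force_high_level:
            raise ValueError("force_low_level must be below force_high_level")


@dataclass
class StrideEvents:
    """Outcome of acceleration-based stride detection."""

    zero_crossings: np.ndarray       # sample indices
    locking_period_s: float
    peak_indices: np.ndarray         # all candidate peaks (samples)
    peak_values: np.ndarray
    pl: np.ndarray                   # drop to the minimum before (toe-off)
    pr: np.ndarray                   # drop to the minimum after (heel-strike)
    valid: np.ndarray                # bool per candidate
    times: np.ndarray                # candidate peak times, seconds

    @property
    def valid_indices(self) -> np.ndarray:
        return self.peak_indices[self.valid]

    @property
    def valid_times(self) -> np.ndarray:
        return self.times[self.valid]

    @property
    def stride_boundaries(self) -> list[tuple[float, float]]:
        vt = self.valid_times
        return [(float(vt[i]), float(vt[i + 1])) for i in range(vt.size - 1)]

    @property
    def n_strides(self) -> int:
        return max(0, int(self.valid.sum()) - 1)


@dataclass(frozen=True)
class GaitParameters:
    """Per-stride spatiotemporal parameters."""

    stride_time_s: np.ndarray
    cadence_steps_min: np.ndarray
    stride_length_m: np.ndarray
    stride_speed_mps: np.ndarray


@dataclass(frozen=True)
class ForceValidation:
    force_cycles: int
    acceleration_strides: int
    agreement: bool
    discrepancy: int


def normalize_recording(
    rec: InsoleRecording, force_subset: tuple[int, ...] | None = None
) -> NormalizedRecording:
    """Z-score Ay (population SD) and scale the summed force to unit maximum.

    ``force_subset`` selects which FSR channels enter the total (supporting
    the 4 -> 3 -> 2 sensor-reduction configurations); default all channels.
    """
    if force_subset is None:
        force_subset = tuple(range(rec.n_channels))
    force_subset = tuple(int(c) for c in force_subset)
    if any(c < 0 or c >= rec.n_channels for c in force_subset):
        raise ValueError("force_subset channel out of range")
    sd = float(np.std(rec.ay))
    if sd == 0:
        raise ValueError("constant Ay cannot be normalized")
    ay = (rec.ay - rec.ay.mean()) / sd
    total = rec.forces[:, force_subset].sum(axis=1)
    peak = float(total.max())
    if not peak > 0:
        raise ValueError("total force has no positive maximum")
    return NormalizedRecording(
        time=rec.time,
        ay=ay,
        ay_raw=rec.ay.copy(),
        total_force=total / peak,
        sample_rate_hz=rec.sample_rate_hz,
        force_subset=force_subset,
    )


def lowpass_ay(
    ay: np.ndarray, fs: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Median filter then zero-phase Butterworth low-pass."""
    config = config or PreprocessConfig()
    x = np.asarray(ay, dtype=float)
    if x.size <= 3 * config.median_window:
        raise ValueError("signal too short for the median window")
    if config.butterworth_cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    x = medfilt(x, kernel_size=config.median_window)
    b, a = butter(
        config.butterworth_order, config.butterworth_cutoff_hz, fs=fs, btype="low"
    )
    return filtfilt(b, a, x)


def locking_period(ay_filtered: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Zero crossings and the locking period (mean inter-crossing interval).

    A crossing is a sign change between consecutive samples (exact zeros
    inherit the preceding sign).  Requires at least two crossings.
    """
    x = np.asarray(ay_filtered, dtype=float)
    s = np.sign(x)
    # propagate the previous sign through exact zeros
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    crossings = np.flatnonzero(s[:-1] * s[1:] < 0)
    if crossings.size < 2:
        raise ValueError("need at least 2 zero crossings to set a locking period")
    lockp = float(np.mean(np.diff(crossings))) / fs
    return crossings, lockp


def _flank_drops(
    x: np.ndarray, peak_idx: int, half_win: int
) -> tuple[float, float]:
    lo = max(0, peak_idx - half_win)
    hi = min(x.size, peak_idx + half_win + 1)
    before = x[lo : peak_idx + 1]
    after = x[peak_idx:hi]
    pl = float(x[peak_idx] - before.min())
    pr = float(x[peak_idx] - after.min())
    return pl, pr


def detect_stride_peaks(
    ay_filtered: np.ndarray,
    fs: float,
    lockp: float,
    config: PreprocessConfig | None = None,
) -> StrideEvents:
    """Locking-period peak detection with shape and gap validation.

    Candidates are the local maxima of the filtered signal.  Around each, a
    lockP-sized window yields the drops PL (to the toe-off minimum before)
    and PR (to the heel-strike minimum after).  A candidate is valid when

    * its smaller flank drop reaches ``shape_similarity_frac`` of the
      largest flank drop among candidates (shape similarity to the dominant
      heel-strike peak; rejects contralateral-step bumps and noise), and
    * scanning left to right, its gap to the previously retained peak
      respects lockP <= gap <= Max_time (a too-close follower is zeroed, and
      a follower beyond Max_time starts a new bout and is kept).
    """
    config = config or PreprocessConfig()
    x = np.asarray(ay_filtered, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    half_win = int(round(lockp * fs / 2))
    if half_win < 1:
        raise ValueError("locking period shorter than 2 samples")

    interior = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    cand = np.flatnonzero(interior) + 1
    if cand.size == 0:
        empty = np.array([], dtype=int)
        return StrideEvents(
            zero_crossings=empty, locking_period_s=lockp,
            peak_indices=empty, peak_values=np.array([]),
            pl=np.array([]), pr=np.array([]),
            valid=np.array([], dtype=bool), times=np.array([]),
        )

    pl = np.empty(cand.size)
    pr = np.empty(cand.size)
    for j, idx in enumerate(cand):
        pl[j], pr[j] = _flank_drops(x, int(idx), half_win)

    flank = np.minimum(pl, pr)
    valid = flank >= config.shape_similarity_frac * flank.max()
    if config.peak_threshold_frac is not None:
        valid &= x[cand] >= config.peak_threshold_frac * x.max()

    # Eq.-2 style gap screening on the shape-valid peaks, left to right.
    times = cand / fs
    max_gap = config.max_stride_time_s
    last_kept = None
    for j in range(cand.size):
        if not valid[j]:
            continue
        if last_kept is None:
            last_kept = j
            continue
        gap = times[j] - times[last_kept]
        if gap < lockp:
            valid[j] = False  # too close to the previous retained peak
        else:
            # gaps beyond Max_time delimit separate walking bouts; the
            # peak remains valid and restarts the scan
            last_kept = j

    return StrideEvents(
        zero_crossings=np.array([], dtype=int),
        locking_period_s=lockp,
        peak_indices=cand,
        peak_values=x[cand],
        pl=pl,
        pr=pr,
        valid=valid,
        times=times,
    )


def _hysteresis_states(
    f: np.ndarray, high: float, low: float
) -> np.ndarray:
    """-1/+1 stance-swing state with hysteresis, 0 before the first crossing."""
    state = 0
    out = np.empty(f.size, dtype=int)
    for i, v in enumerate(f):
        if v >= high:
            state = 1
        elif v <= low:
            state = -1
        out[i] = state
    return out


def validate_with_force(
    total_force: np.ndarray,
    events: StrideEvents,
    fs: float,
    config: PreprocessConfig | None = None,
) -> ForceValidation:
    """Check the acceleration stride count against force stance/swing cycles.

    A cycle is a completed stance -> swing -> stance excursion of the
    normalized total force (hysteresis at the high/low levels); walking
    produces one cycle per stride of the instrumented foot.
    """
    config = config or PreprocessConfig()
    f = np.asarray(total_force, dtype=float)
    if not np.isclose(f.max(), 1.0, atol=0.05):
        raise ValueError("total force does not look normalized (max != 1)")
    states = _hysteresis_states(f, config.force_high_level, config.force_low_level)
    # count swing->stance returns that were preceded by a stance
    cycles = 0
    seen_stance = False
    prev = 0
    for s in states:
        if s == 1 and prev == -1 and seen_stance:
            cycles += 1
        if s == 1:
            seen_stance = True
        prev = s
    n_acc = events.n_strides
    return ForceValidation(
        force_cycles=cycles,
        acceleration_strides=n_acc,
        agreement=cycles == n_acc,
        discrepancy=abs(cycles - n_acc),
    )


def stance_onsets(
    total_force: np.ndarray, fs: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Times of swing-to-stance transitions of the normalized total force.

    Each onset marks a heel strike of the instrumented foot; successive
    onsets bound one stride, giving a force-only stride-time estimate for
    cross-checking the acceleration-based one (e.g. in reduced-FSR
    configurations).
    """
    config = config or PreprocessConfig()
    f = np.asarray(total_force, dtype=float)
    states = _hysteresis_states(f, config.force_high_level, config.force_low_level)
    onsets = []
    prev = 0
    for i, s in enumerate(states):
        if s == 1 and prev == -1:
            onsets.append(i / fs)
        prev = s
    return np.asarray(onsets)


def detect_sts_phases(
    total_force: np.ndarray, fs: float, smooth_s: float = 0.3
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Sit-to-stand and stand-to-sit intervals from the total-force ramps.

    Sit-to-stand is the first sustained loading ramp from the initial
    low-force sitting plateau up to first attainment of the standing level;
    stand-to-sit is the final unloading ramp down to the ending plateau.
    Levels are taken at 5% / 95% of the plateau-to-standing span.
    """
    f = np.asarray(total_force, dtype=float)
    n = f.size
    if n < int(2 * fs):
        raise ValueError("force series too short")
    win = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(win) / win
    fsm = np.convolve(f, kernel, mode="same")

    head = fsm[: int(fs)]
    tail = fsm[-int(fs) :]
    sit0 = float(np.median(head))
    sit1 = float(np.median(tail))
    stand = float(np.quantile(fsm, 0.95))

    span0 = stand - sit0
    if span0 <= 0.1 * max(stand, 1e-9):
        raise ValueError("no sit-to-stand rise found")
    lo_level = sit0 + 0.05 * span0
    hi_level = sit0 + 0.95 * span0
    above = np.flatnonzero(fsm >= hi_level)
    if above.size == 0:
        raise ValueError("no sit-to-stand rise found")
    i_end = int(above[0])
    below = np.flatnonzero(fsm[:i_end] <= lo_level)
    i_start = int(below[-1]) if below.size else 0
    s2st = (i_start / fs, i_end / fs)

    span1 = stand - sit1
    if span1 <= 0.1 * max(stand, 1e-9):
        raise ValueError("no stand-to-sit decline found")
    lo_level = sit1 + 0.05 * span1
    hi_level = sit1 + 0.95 * span1
    # final unloading ramp: last attainment of the standing level, then the
    # first return to the ending low plateau (scanned from the end so the
    # per-stride swing dips during walking are never picked up)
    above = np.flatnonzero(fsm >= hi_level)
    above = above[above > i_end]
    if above.size == 0:
        raise ValueError("no stand-to-sit decline found")
    j_start = int(above[-1])
    below = np.flatnonzero(fsm <= lo_level)
    below = below[below > j_start]
    if below.size == 0:
        raise ValueError("no stand-to-sit decline found")
    j_end = int(below[0])
    st2s = (j_start / fs, j_end / fs)
    return s2st, st2s


def compute_gait_parameters(
    events: StrideEvents,
    stride_lengths: np.ndarray,
    steps_per_stride: int = 2,
) -> GaitParameters:
    """Stride time, cadence and stride speed for each detected stride.

    Cadence is reported in steps/min: 60 x steps-per-stride / stride time
    (two steps per stride for ordinary gait).
    """
    bounds = events.stride_boundaries
    sl = np.asarray(stride_lengths, dtype=float)
    if sl.size != len(bounds):
        raise ValueError("stride_lengths must align with stride boundaries")
    st = np.array([b - a for a, b in bounds])
    if np.any(st <= 0):
        raise ValueError("non-positive stride time")
    cadence = 60.0 * steps_per_stride / st
    return GaitParameters(
        stride_time_s=st,
        cadence_steps_min=cadence,
        stride_length_m=sl,
        stride_speed_mps=sl / st,
    )
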