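"""Synthetic paired radar + insole TUG trials with known ground truth.

No public recordings of combined UWB-radar/instrumented-insole TUG trials
exist, so the package ships a generator that emulates the 3 m test layout:
the radar sits ``D_pos`` behind the chair; the subject sits (quasi-static
jittered range), rises by ``d_qs`` (sit-to-stand), walks stride-by-stride
out to ``D_pos + walk_distance``, turns on a range plateau, walks back,
and sits down again.  The insole stream carries a quasi-periodic
anteroposterior acceleration with one dominant heel-strike peak per stride
(flanked by toe-off and heel-strike minima, plus a small contralateral-step
bump so the signal crosses zero twice per step) and FSR force channels that
are high in stance, near zero in swing, and at partial load while seated.

Ground-truth event times t0..t5 are the analytic crossing times of the
noise-free trajectory under the segmenter's own geometric definitions
(D > D_pos, D >= D_pos + d_qs, ...); the motion-phase start/end times are
stored separately in ``GroundTruth.motion_phases``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .insole import InsoleRecording
from .radar import RadarTrace

__all__ = ["SimulationParams", "GroundTruth", "simulate_tug", "simulate_quasi_static"]

# Per-stride anteroposterior acceleration template (phase, value), phase 0 at
# heel strike.  Sign pattern + - + - gives exactly 4 zero crossings per
# stride (two per step); the deep minimum at phase 0.80 (pre-heel-strike)
# is deeper than the toe-off one at 0.20, so PL != PR generically.
_AY_KNOTS = (
    (0.00, 2.0),
    (0.10, 0.2),
    (0.20, -1.1),
    (0.32, -0.3),
    (0.44, -0.15),
    (0.52, 0.35),
    (0.60, -0.15),
    (0.72, -0.4),
    (0.80, -1.5),
    (0.90, 0.2),
)
_AY_SPAN = 3.5  # template max - min at unit amplitude scale

# amplitude scale at the reference stride length, chosen so the Weinberg
# estimator with K = 0.9763 is unbiased at the reference stride
_SL_REF = 1.3
_AMP_REF = (_SL_REF / 0.9763) ** 4 / _AY_SPAN


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class SimulationParams:
    """Geometry, gait statistics, rates and noise levels of one TUG trial.

    Defaults emulate the 3 m layout (radar 0.5 m behind the chair, 0.3 m
    standing offset) walked by a healthy adult: 1.3 m strides of 1.1 s at
    ~1.2 m/s, a 2 s turn at reduced speed, a 5 Hz radar and a 100 Hz insole.
    Sensor noise defaults reflect the radar's ~3 cm ranging jitter plus body
    sway, and small accelerometer/FSR noise.
    """

    radar_offset_m: float = 0.5
    standing_offset_m: float = 0.3
    walk_distance_m: float = 3.0
    sit_setback_m: float = 0.1      # seated torso sits this far behind D_pos
    sit_duration_s: float = 3.5
    s2st_duration_s: float = 1.5
    st2s_duration_s: float = 1.5
    pre_sit_pause_s: float = 0.7    # standing still at the chair before sitting
    turn_duration_s: float = 2.0
    final_sit_duration_s: float = 3.0
    stride_length_m: float = 1.3
    stride_length_sd_m: float = 0.05
    stride_time_s: float = 1.1
    stride_time_sd_s: float = 0.04
    speed_modulation: float = 0.7   # within-stride velocity swing (0..1)
    turn_amp_frac: float = 0.6      # turn-stride Ay amplitude vs walking
    radar_rate_hz: float = 5.0
    insole_rate_hz: float = 100.0
    radar_noise_sd_m: float = 0.03
    ay_noise_sd: float = 0.05
    force_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "radar_offset_m", "standing_offset_m", "walk_distance_m",
            "sit_duration_s", "s2st_duration_s", "st2s_duration_s",
            "turn_duration_s", "stride_length_m", "stride_time_s",
            "radar_rate_hz", "insole_rate_hz",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("stride_length_sd_m", "stride_time_sd_s",
                     "radar_noise_sd_m", "ay_noise_sd", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stride_length_m > self.walk_distance_m:
            raise ValueError("stride longer than the walk distance is infeasible")
        if not self.walk_distance_m > self.standing_offset_m:
            raise ValueError("walk_distance_m must exceed standing_offset_m")


@dataclass
class GroundTruth:
    """Everything the generator knows about the trial it produced."""

    t0: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    motion_phases: dict[str, tuple[float, float]]
    heel_strikes: np.ndarray          # stride boundaries incl. final contact
    toe_offs: np.ndarray
    stride_lengths: np.ndarray        # per stride, meters
    stride_times: np.ndarray          # per stride, seconds
    stride_labels: list[str]          # walk_forward / turn / walk_back
    n_strides: int

    @property
    def event_times(self) -> np.ndarray:
        return np.array([self.t0, self.t1, self.t2, self.t3, self.t4, self.t5])

    @property
    def stride_boundaries(self) -> list[tuple[float, float]]:
        hs = self.heel_strikes
        return [(float(hs[i]), float(hs[i + 1])) for i in range(len(hs) - 1)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["heel_strikes"] = [float(x) for x in self.heel_strikes]
        d["toe_offs"] = [float(x) for x in self.toe_offs]
        d["stride_lengths"] = [float(x) for x in self.stride_lengths]
        d["stride_times"] = [float(x) for x in self.stride_times]
        d["motion_phases"] = {
            k: [float(a), float(b)] for k, (a, b) in self.motion_phases.items()
        }
        return d


def _draw_strides(
    rng: np.random.Generator, advance: float, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Stride lengths summing exactly to ``advance`` plus matching times."""
    n = max(1, round(advance / params.stride_length_m))
    sl = rng.normal(params.stride_length_m, params.stride_length_sd_m, n)
    sl = np.clip(sl, 0.3 * params.stride_length_m, None)
    sl *= advance / sl.sum()
    st = rng.normal(params.stride_time_s, params.stride_time_sd_s, n)
    st = np.clip(st, 0.5 * params.stride_time_s, None)
    return sl, st


def _stride_advance(u: np.ndarray, beta: float) -> np.ndarray:
    """Within-stride displacement fraction with modulated, nonzero velocity."""
    u = np.clip(u, 0.0, 1.0)
    return u - beta * np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


class _Trajectory:
    """Piecewise analytic range trajectory D(t) of the trial."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        p = params
        self.p = p
        self.sit_level = p.radar_offset_m - p.sit_setback_m
        self.stand_level = p.radar_offset_m + p.standing_offset_m
        self.far_level = p.radar_offset_m + p.walk_distance_m
        advance = p.walk_distance_m - p.standing_offset_m

        self.sl_wf, self.st_wf = _draw_strides(rng, advance, p)
        self.sl_wb, self.st_wb = _draw_strides(rng, advance, p)

        self.t_s2st = p.sit_duration_s
        self.t_walkf = self.t_s2st + p.s2st_duration_s
        self.t_turn = self.t_walkf + float(self.st_wf.sum())
        self.t_walkb = self.t_turn + p.turn_duration_s
        self.t_walkb_end = self.t_walkb + float(self.st_wb.sum())
        self.t_st2s = self.t_walkb_end + p.pre_sit_pause_s
        self.t_end_motion = self.t_st2s + p.st2s_duration_s
        self.total = self.t_end_motion + p.final_sit_duration_s

        self.hs_wf = self.t_walkf + np.concatenate(([0.0], np.cumsum(self.st_wf)))
        self.hs_wb = self.t_walkb + np.concatenate(([0.0], np.cumsum(self.st_wb)))

    def _walk_distance_at(
        self, t: np.ndarray, hs: np.ndarray, sl: np.ndarray, forward: bool
    ) -> np.ndarray:
        cum = np.concatenate(([0.0], np.cumsum(sl)))
        idx = np.clip(np.searchsorted(hs, t, side="right") - 1, 0, len(sl) - 1)
        u = (t - hs[idx]) / (hs[idx + 1] - hs[idx])
        adv = cum[idx] + sl[idx] * _stride_advance(u, self.p.speed_modulation)
        if forward:
            return self.stand_level + adv
        return self.far_level - adv

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        p = self.p
        d = np.empty_like(t)

        seg = t < self.t_s2st
        d[seg] = self.sit_level
        seg = (t >= self.t_s2st) & (t < self.t_walkf)
        u = (t[seg] - self.t_s2st) / p.s2st_duration_s
        d[seg] = self.sit_level + (self.stand_level - self.sit_level) * _smoothstep(u)
        seg = (t >= self.t_walkf) & (t < self.t_turn)
        d[seg] = self._walk_distance_at(t[seg], self.hs_wf, self.sl_wf, True)
        seg = (t >= self.t_turn) & (t < self.t_walkb)
        u = (t[seg] - self.t_turn) / p.turn_duration_s
        # the subject steps slightly past the walkway end while turning;
        # range stays just beyond far with a gentle sway
        d[seg] = self.far_level + 0.01 + 0.04 * 0.5 * (1 - np.cos(2 * np.pi * u))
        seg = (t >= self.t_walkb) & (t < self.t_walkb_end)
        d[seg] = self._walk_distance_at(t[seg], self.hs_wb, self.sl_wb, False)
        seg = (t >= self.t_walkb_end) & (t < self.t_st2s)
        d[seg] = self.stand_level
        seg = (t >= self.t_st2s) & (t < self.t_end_motion)
        u = (t[seg] - self.t_st2s) / p.st2s_duration_s
        d[seg] = self.stand_level + (self.sit_level - self.stand_level) * _smoothstep(u)
        seg = t >= self.t_end_motion
        d[seg] = self.sit_level
        return d

    def ground_truth(self) -> GroundTruth:
        p = self.p
        # t0 / t5: analytic crossings of D_pos on the s2st / st2s ramps
        def f0(t):
            return float(self(np.array([t]))[0]) - p.radar_offset_m

        t0 = brentq(f0, self.t_s2st + 1e-9, self.t_walkf - 1e-9)
        t5 = brentq(f0, self.t_st2s + 1e-9, self.t_end_motion - 1e-9)

        hs = np.concatenate([self.hs_wf, self.hs_wb])  # turn stride shares ends
        sl_turn = 0.5 * p.stride_length_m
        stride_lengths = np.concatenate([self.sl_wf, [sl_turn], self.sl_wb])
        stride_times = np.concatenate(
            [self.st_wf, [p.turn_duration_s], self.st_wb]
        )
        labels = (
            ["walk_forward"] * len(self.sl_wf)
            + ["turn"]
            + ["walk_back"] * len(self.sl_wb)
        )
        toe_offs = hs[:-1] + 0.20 * _effective_stride_times(stride_times, labels)
        return GroundTruth(
            t0=float(t0),
            t1=float(self.t_walkf),
            t2=float(self.t_turn),
            t3=float(self.t_walkb),
            t4=float(self.t_walkb_end),
            t5=float(t5),
            motion_phases={
                "sit": (0.0, self.t_s2st),
                "sit_to_stand": (self.t_s2st, self.t_walkf),
                "walk_forward": (self.t_walkf, self.t_turn),
                "turn": (self.t_turn, self.t_walkb),
                "walk_back": (self.t_walkb, self.t_walkb_end),
                "stand_to_sit": (self.t_st2s, self.t_end_motion),
                "final_sit": (self.t_end_motion, self.total),
            },
            heel_strikes=hs,
            toe_offs=toe_offs,
            stride_lengths=stride_lengths,
            stride_times=stride_times,
            stride_labels=labels,
            n_strides=len(stride_lengths),
        )


def _effective_stride_times(
    stride_times: np.ndarray, labels: list[str]
) -> np.ndarray:
    """Timescale of each stride's step transients.

    A slow turn stride is a pause between near-normal steps, not a uniformly
    stretched gait cycle, so its heel-strike/toe-off transients keep a
    walking-like timescale (matching the median walking stride time)
    while the low-activity mid-stride stretch absorbs the extra duration.
    """
    walking = np.asarray(
        [st for st, lab in zip(stride_times, labels) if lab != "turn"]
    )
    cap = 1.0 * (np.median(walking) if walking.size else np.median(stride_times))
    return np.minimum(np.asarray(stride_times, dtype=float), cap)


def _warp_phase(phase: float, st_actual: float, st_eff: float) -> float:
    """Knot time offset within a stride, warping only the mid-stride part."""
    if phase <= 0.32:
        return phase * st_eff
    if phase >= 0.60:
        return st_actual - (1.0 - phase) * st_eff
    # middle knots spread linearly over the remaining span
    lo = 0.32 * st_eff
    hi = st_actual - 0.40 * st_eff
    return lo + (phase - 0.32) / 0.28 * (hi - lo)


def _ay_waveform(
    t: np.ndarray, truth: GroundTruth, params: SimulationParams
) -> np.ndarray:
    """Noise-free anteroposterior acceleration on the insole clock."""
    hs = truth.heel_strikes
    # per-stride amplitude: follows stride length for walking strides
    # (stronger push-off for longer strides), reduced for the turn stride
    amps = []
    for sl, lab in zip(truth.stride_lengths, truth.stride_labels):
        if lab == "turn":
            amps.append(params.turn_amp_frac * _AMP_REF)
        else:
            amps.append(_AMP_REF * (sl / _SL_REF) ** 4)
    amps = np.asarray(amps)
    st_eff = _effective_stride_times(truth.stride_times, truth.stride_labels)

    knot_t: list[float] = []
    knot_v: list[float] = []
    # gait-initiation transient: give the first heel-strike peak the same
    # local context as an interior one (pre-peak dip and shoulder)
    st0 = st_eff[0]
    a0 = amps[0]
    for dt, val in ((-0.30, -0.02), (-0.20, -1.5 * a0), (-0.10, 0.2 * a0)):
        knot_t.append(hs[0] + dt * st0)
        knot_v.append(val)
    for i in range(len(hs) - 1):
        st = hs[i + 1] - hs[i]
        a = amps[i]
        for phase, val in _AY_KNOTS:
            knot_t.append(hs[i] + _warp_phase(phase, st, st_eff[i]))
            knot_v.append(a * val)
    # final heel strike with an interior-like termination transient
    a_last = amps[-1]
    st_last = st_eff[-1]
    knot_t.append(hs[-1])
    knot_v.append(a_last * 2.0)
    for dt, val in (
        (0.10, 0.2 * a_last),
        (0.20, -1.1 * a_last),
        (0.32, -0.3 * a_last),
        (0.45, -0.02),
        (0.60, 0.0),
    ):
        knot_t.append(hs[-1] + dt * st_last)
        knot_v.append(val)

    spline = PchipInterpolator(np.asarray(knot_t), np.asarray(knot_v))
    ay = np.zeros_like(t)
    mask = (t >= knot_t[0]) & (t <= knot_t[-1])
    ay[mask] = spline(t[mask])
    return ay


def _force_waveform(
    t: np.ndarray, truth: GroundTruth, params: SimulationParams
) -> np.ndarray:
    """Noise-free normalized-total-force profile (max 1) on the insole clock."""
    sit, stand, swing = 0.25, 1.0, 0.05
    ramp_w = 0.05  # s, half-width of the heel-strike loading ramp
    p = params
    s2st = truth.motion_phases["sit_to_stand"]
    st2s = truth.motion_phases["stand_to_sit"]

    knot_t = [0.0, s2st[0], s2st[1]]
    knot_v = [sit, sit, stand]  # linear loading ramp while standing up
    hs = truth.heel_strikes
    for i in range(len(hs) - 1):
        st = hs[i + 1] - hs[i]
        fall = hs[i] + 0.62 * st
        knot_t += [fall - ramp_w, fall + ramp_w, hs[i + 1] - ramp_w, hs[i + 1] + ramp_w]
        knot_v += [stand, swing, swing, stand]
    knot_t += [st2s[0], st2s[1], truth.motion_phases["final_sit"][1]]
    knot_v += [stand, sit, sit]
    return np.interp(t, np.asarray(knot_t), np.asarray(knot_v))


def simulate_tug(
    params: SimulationParams | None = None,
) -> tuple[RadarTrace, InsoleRecording, GroundTruth]:
    """Generate one paired radar + insole TUG trial.

    Returns the radar range trace (with measurement noise and band-limited
    body-sway micro-motion), the insole recording (3 FSR channels splitting
    the total force under heel-medial/heel-lateral/metatarsal pads), and the
    ground truth.  Fully determined by ``params`` including its seed.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    traj = _Trajectory(params, rng)
    truth = traj.ground_truth()

    # --- radar stream ---
    n_r = int(np.floor(traj.total * params.radar_rate_hz)) + 1
    t_r = np.arange(n_r) / params.radar_rate_hz
    d = traj(t_r)
    if params.radar_noise_sd_m > 0:
        white = rng.normal(0.0, params.radar_noise_sd_m, n_r)
        sway = rng.normal(0.0, params.radar_noise_sd_m, n_r)
        kernel = np.ones(5) / 5.0
        sway = np.convolve(sway, kernel, mode="same")
        d = d + white + 0.5 * sway
    radar = RadarTrace(t_r, np.maximum(d, 0.0))

    # --- insole stream ---
    n_i = int(np.floor(traj.total * params.insole_rate_hz)) + 1
    t_i = np.arange(n_i) / params.insole_rate_hz
    ay = _ay_waveform(t_i, truth, params)
    if params.ay_noise_sd > 0:
        ay = ay + rng.normal(0.0, params.ay_noise_sd, n_i)
    total_force = _force_waveform(t_i, truth, params)
    shares = np.array([0.45, 0.25, 0.30])  # heel-medial, heel-lateral, metatarsal
    forces = total_force[:, None] * shares[None, :]
    if params.force_noise_sd > 0:
        forces = forces + rng.normal(0.0, params.force_noise_sd, forces.shape)
        forces = np.maximum(forces, 0.0)
    insole = InsoleRecording(
        time=t_i, ay=ay, forces=forces, sample_rate_hz=params.insole_rate_hz
    )
    return radar, insole, truth


def simulate_quasi_static(
    duration_s: float, params: SimulationParams | None = None,
    jitter_sd_m: float = 0.01,
) -> RadarTrace:
    """A seated/standing-still range trace: constant range plus jitter.

    For jitter below ~0.02 m the Kalman velocity stays under the 0.4 m/s
    walking threshold, so the segmenter reports quasi-static.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    n = int(np.floor(duration_s * params.radar_rate_hz)) + 1
    t = np.arange(n) / params.radar_rate_hz
    level = params.radar_offset_m - params.sit_setback_m
    d = np.full(n, level)
    if jitter_sd_m > 0:
        d = d + rng.normal(0.0, jitter_sd_m, n)
    return RadarTrace(t, np.maximum(d, 0.0))
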