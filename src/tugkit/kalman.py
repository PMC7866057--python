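"""Constant-acceleration Kalman filter for range-only tracking.

A UWB radar reports the range to the subject once per frame.  Differentiating
that noisy range directly amplifies the noise, especially in the low-velocity
portions of a TUG trial (sitting, turning), so gait velocity is instead
estimated with a Kalman filter whose state is (position, velocity,
acceleration).  The filter assumes a discrete constant-acceleration motion
model and a scalar range measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FilterConfig", "TrackState", "kf_step", "estimate_kinematics"]


def _default_q0() -> np.ndarray:
    return np.diag([0.04, 0.01, 0.01])


@dataclass(frozen=True)
class FilterConfig:
    """Filter tuning.

    Parameters
    ----------
    sample_interval_s : float
        Tracking update interval Ts in seconds (default 0.2 s, i.e. a 5 Hz
        radar frame rate).
    measurement_noise : float
        Scalar range-measurement variance R in m^2 (default 0.04, the square
        of the radar's ~0.2 m effective ranging noise).
    process_noise : ndarray, shape (3, 3)
        Process noise covariance Q, held constant at its initial value
        diag(0.04, 0.01, 0.01).
    """

    sample_interval_s: float = 0.2
    measurement_noise: float = 0.04
    process_noise: np.ndarray = field(default_factory=_default_q0)

    def __post_init__(self) -> None:
        if not self.sample_interval_s > 0:
            raise ValueError("sample_interval_s must be > 0")
        if not self.measurement_noise > 0:
            raise ValueError("measurement_noise must be > 0")
        q = np.asarray(self.process_noise, dtype=float)
        if q.shape != (3, 3):
            raise ValueError("process_noise must be a 3x3 matrix")
        if np.any(np.diag(q) < 0):
            raise ValueError("process_noise diagonal entries must be >= 0")
        object.__setattr__(self, "process_noise", q)

    @property
    def transition_matrix(self) -> np.ndarray:
        ts = self.sample_interval_s
        return np.array(
            [[1.0, ts, 0.5 * ts * ts], [0.0, 1.0, ts], [0.0, 0.0, 1.0]]
        )


@dataclass
class TrackState:
    """Kalman state: position (m), velocity (m/s), acceleration (m/s^2)."""

    position: float
    velocity: float = 0.0
    acceleration: float = 0.0
    covariance: np.ndarray = field(default_factory=_default_q0)

    def __post_init__(self) -> None:
        p = np.asarray(self.covariance, dtype=float)
        if p.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        if not np.allclose(p, p.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        self.covariance = 0.5 * (p + p.T)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.position, self.velocity, self.acceleration])


_H = np.array([[1.0, 0.0, 0.0]])


def kf_step(state: TrackState, measurement: float, config: FilterConfig) -> TrackState:
    """One predict-then-update cycle on a scalar range measurement.

    Prediction propagates the state through the constant-acceleration model;
    the update blends the predicted position with the measurement through the
    Kalman gain.  The covariance is re-symmetrised after the Joseph-form
    update so it stays symmetric positive semi-definite over long runs.
    """
    if not np.isfinite(measurement):
        raise ValueError("measurement must be finite")
    f = config.transition_matrix
    x = f @ state.vector
    p = f @ state.covariance @ f.T + config.process_noise

    innovation = measurement - float(x[0])
    s = float(p[0, 0]) + config.measurement_noise
    gain = (p @ _H.T) / s  # (3, 1)

    x = x + gain[:, 0] * innovation
    ikh = np.eye(3) - gain @ _H
    p = ikh @ p @ ikh.T + gain @ gain.T * config.measurement_noise
    p = 0.5 * (p + p.T)
    return TrackState(x[0], x[1], x[2], p)


def estimate_kinematics(
    positions: np.ndarray, config: FilterConfig | None = None
) -> np.ndarray:
    """Filter a uniformly sampled range series.

    Parameters
    ----------
    positions : array of shape (n,)
        Range measurements in meters, sampled every ``config.sample_interval_s``.

    Returns
    -------
    ndarray of shape (n, 3)
        Filtered (position, velocity, acceleration) per sample.  The filter is
        initialised at the first measurement with zero velocity/acceleration
        and covariance Q + R*I (the R*I floor keeps the filter identifiable
        when Q is zero), so early velocity estimates carry a short burn-in.
    """
    if config is None:
        config = FilterConfig()
    z = np.asarray(positions, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("need a 1-D series of at least 2 samples")
    if not np.all(np.isfinite(z)):
        raise ValueError("positions must be finite")

    p0 = config.process_noise + config.measurement_noise * np.eye(3)
    state = TrackState(z[0], 0.0, 0.0, p0)
    out = np.empty((z.size, 3))
    out[0] = state.vector
    for k in range(1, z.size):
        state = kf_step(state, z[k], config)
        out[k] = state.vector
    return out
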