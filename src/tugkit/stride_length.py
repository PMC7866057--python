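"""Acceleration-based stride-length estimators and their calibration.

Three empirical estimators map the anteroposterior acceleration over one
stride window (raw sensor units, not the z-scored copy used for
segmentation) to a stride length:

* approach 1 (mean-of-absolute): SL = K1 * (mean |Ay|)^(1/3),
* approach 2 (Weinberg):         SL = K2 * (Ay_max - Ay_min)^(1/4),
* approach 3 (Scarlett):         SL = K3 * mean((Ay - Ay_min)/(Ay_max - Ay_min)).

K1 is a fixed unit-conversion constant (0.98).  K2 and K3 are tied to a
single free calibration coefficient K (K2 = K, K3 = 2K), obtained as the
mean ratio of estimated to reference distances; the default K = 0.9763.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationConstants",
    "StrideWindow",
    "sl_mean_abs",
    "sl_weinberg",
    "sl_scarlett",
    "estimate_all",
    "calibrate_k",
    "refine_constants",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Unit-conversion constants for the three estimators.

    ``k`` is the single free coefficient; ``k2 = k`` and ``k3 = 2 k`` are
    maintained as a linked constraint.  ``k1`` is fixed independently.
    """

    k1: float = 0.98
    k: float = 0.9763

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k > 0):
            raise ValueError("calibration constants must be positive")

    @property
    def k2(self) -> float:
        return self.k

    @property
    def k3(self) -> float:
        return 2.0 * self.k

    def with_k(self, k: float) -> "CalibrationConstants":
        return CalibrationConstants(k1=self.k1, k=k)


@dataclass(frozen=True)
class StrideWindow:
    """Raw y-acceleration samples spanning one stride."""

    ay: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ay, dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("stride window needs at least 2 samples")
        if not np.all(np.isfinite(a)):
            raise ValueError("stride window must be finite")
        object.__setattr__(self, "ay", a)

    @property
    def n(self) -> int:
        return self.ay.size


def sl_mean_abs(window: StrideWindow, k1: float = 0.98) -> float:
    """Approach 1: cube root of the mean absolute acceleration, scaled by K1."""
    return float(k1 * np.cbrt(np.mean(np.abs(window.ay))))


def sl_weinberg(window: StrideWindow, k2: float = 0.9763) -> float:
    """Approach 2: fourth root of the acceleration peak-to-peak range.

    The peak-to-peak range proxies the vertical hip excursion driving the
    step, hence the quarter-power law.
    """
    return float(k2 * (window.ay.max() - window.ay.min()) ** 0.25)


def sl_scarlett(window: StrideWindow, k3: float = 2 * 0.9763) -> float:
    """Approach 3: mean min-max-normalized acceleration, scaled by K3.

    Undefined for a constant window (zero amplitude range); the result is
    confined to (0, k3) for any non-constant window.
    """
    span = window.ay.max() - window.ay.min()
    if span <= 0:
        raise ValueError("constant window: amplitude range is zero")
    return float(k3 * np.mean((window.ay - window.ay.min()) / span))


def estimate_all(
    window: StrideWindow, constants: CalibrationConstants | None = None
) -> dict[str, float]:
    """All three estimates for one stride window, keyed by approach."""
    c = constants or CalibrationConstants()
    return {
        "mean_abs": sl_mean_abs(window, c.k1),
        "weinberg": sl_weinberg(window, c.k2),
        "scarlett": sl_scarlett(window, c.k3),
    }


def calibrate_k(estimated: np.ndarray, real: np.ndarray) -> float:
    """Calibration coefficient: mean ratio of estimated to real distances."""
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(real, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError("estimated and real series must have equal nonzero length")
    if np.any(ref <= 0):
        raise ValueError("real distances must be positive")
    return float(np.mean(est / ref))


def refine_constants(
    windows: list[StrideWindow],
    real_lengths: np.ndarray,
    constants: CalibrationConstants | None = None,
) -> CalibrationConstants:
    """Re-calibrate K from stride windows with known reference lengths.

    The Weinberg estimates under the current K are compared with the
    reference lengths; K is divided by their mean ratio so that the
    calibrated estimates are unbiased on the calibration set.
    """
    c = constants or CalibrationConstants()
    est = np.array([sl_weinberg(w, c.k2) for w in windows])
    ratio = calibrate_k(est, real_lengths)
    return c.with_k(c.k / ratio)
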