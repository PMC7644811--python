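"""Motor-primitive geometrics: center of activity and FWHM.

The center of activity (CoA) treats the normalized gait cycle as a
circle: point t of the p = 200 cycle points sits at angle
theta_t = 2*pi*t/p, and the CoA is the angle of the activation's
circular center of mass,

    A = sum(cos(theta_t) * P_t),  B = sum(sin(theta_t) * P_t),
    CoA = atan2(B, A)  (mod 2*pi),

computed cycle by cycle and aggregated across a trial's cycles by the
circular mean. The full width at half maximum (FWHM) is, per cycle
after subtracting the cycle minimum, the number of points strictly
exceeding half the cycle maximum.
"""

from __future__ import annotations

import numpy as np

from .datatypes import POINTS_PER_CYCLE


class UndefinedCoAError(ValueError):
    """Raised when a cycle's activation is uniform (A = B = 0)."""


def _cycles(primitive: np.ndarray, points_per_cycle: int) -> np.ndarray:
    primitive = np.asarray(primitive, dtype=float)
    if primitive.ndim == 1:
        if primitive.size % points_per_cycle:
            raise ValueError("primitive length is not a whole number of cycles")
        return primitive.reshape(-1, points_per_cycle)
    if primitive.ndim == 2 and primitive.shape[1] == points_per_cycle:
        return primitive
    raise ValueError("expected a 1-D primitive or (n_cycles, p) array")


def center_of_activity(cycle: np.ndarray, points_per_cycle: int | None = None) -> float:
    """CoA angle in [0, 2*pi) of a single activation cycle."""
    cycle = np.asarray(cycle, dtype=float)
    p = points_per_cycle or cycle.size
    theta = 2.0 * np.pi * np.arange(p) / p
    a = float(np.sum(np.cos(theta) * cycle))
    b = float(np.sum(np.sin(theta) * cycle))
    if np.hypot(a, b) < 1e-12 * max(1.0, float(np.abs(cycle).sum())):
        raise UndefinedCoAError("uniform activation: CoA undefined (A = B = 0)")
    return float(np.arctan2(b, a) % (2.0 * np.pi))


def coa_to_points(angle: float, points_per_cycle: int = POINTS_PER_CYCLE) -> float:
    """Convert a CoA angle to its normalized-cycle point equivalent."""
    return angle / (2.0 * np.pi) * points_per_cycle


def trial_coa(
    primitive: np.ndarray, points_per_cycle: int = POINTS_PER_CYCLE
) -> tuple[float, np.ndarray]:
    """Per-cycle CoAs and their circular mean over the trial.

    Returns ``(mean_angle, per_cycle_angles)``; the mean respects the
    wrap-around at the cycle boundary (resultant-vector average).
    """
    cycles = _cycles(primitive, points_per_cycle)
    angles = np.array([center_of_activity(c) for c in cycles])
    mean = float(np.arctan2(np.sin(angles).mean(), np.cos(angles).mean()) % (2 * np.pi))
    return mean, angles


def fwhm(cycle: np.ndarray) -> int:
    """Points strictly above half maximum after min subtraction."""
    cycle = np.asarray(cycle, dtype=float)
    v = cycle - cycle.min()
    vmax = v.max()
    if vmax == 0:
        return 0
    return int(np.sum(v > 0.5 * vmax))


def trial_fwhm(
    primitive: np.ndarray, points_per_cycle: int = POINTS_PER_CYCLE
) -> tuple[float, np.ndarray]:
    """Per-cycle FWHM values and their mean over the trial."""
    cycles = _cycles(primitive, points_per_cycle)
    values = np.array([fwhm(c) for c in cycles], dtype=float)
    return float(values.mean()), values


def halfmax_heatmap(
    primitive: np.ndarray, points_per_cycle: int = POINTS_PER_CYCLE
) -> np.ndarray:
    """Per-time-point fraction of cycles above their half maximum.

    Each cycle is min-subtracted and thresholded at half its maximum;
    the boolean exceedances are averaged across cycles, giving one
    value in [0, 1] per normalized time point. The sum of this curve
    over the cycle equals the trial's mean FWHM.
    """
    cycles = _cycles(primitive, points_per_cycle)
    v = cycles - cycles.min(axis=1, keepdims=True)
    vmax = v.max(axis=1, keepdims=True)
    safe = np.where(vmax == 0, 1.0, vmax)
    exceed = v > 0.5 * safe
    exceed[vmax[:, 0] == 0] = False
    return exceed.mean(axis=0)
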