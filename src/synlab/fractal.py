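"""Rescaled-range (R/S) fractal analysis of motor primitives.

For a series of length n the rescaled range of a segment is the range
(max - min) of the mean-centered cumulative sum divided by the
segment's standard deviation. R/S is averaged over consecutive
non-overlapping segments at window sizes N = n, n/2, n/4, ...
stopping before N falls below the normalized cycle period (200
points). The Hurst exponent H is the slope of log(R/S) against
log(N): H = 0.5 for a memoryless series, H > 0.5 for persistent
(long-memory) series and H < 0.5 for anti-persistent series such as
quasi-periodic motor primitives.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .datatypes import HurstResult, SynergyModel


class ConstantSegmentError(ValueError):
    """Raised when a segment has zero variance (R/S undefined)."""


def rescaled_range(segment: np.ndarray, ddof: int = 0) -> float:
    """R/S of one segment.

    The standard deviation uses the population convention (``ddof=0``)
    by default; the log-log slope is insensitive to this choice at the
    lengths used here.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("segment too short")
    s = segment.std(ddof=ddof)
    if s == 0:
        raise ConstantSegmentError("constant segment: S = 0")
    z = np.cumsum(segment - segment.mean())
    return float((z.max() - z.min()) / s)


def hurst_rs(
    series: np.ndarray,
    min_window: int = 200,
    warn_fit_r2: float = 0.9,
) -> HurstResult:
    """Hurst exponent of a series by rescaled-range analysis.

    Window sizes are n, n//2, n//4, ... down to (and including) the
    first size >= ``min_window``; within each size the series is cut
    into consecutive non-overlapping segments (trailing remainder
    discarded), R/S is averaged across segments, and H is the
    ordinary-least-squares slope of log(R/S) on log(N).
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    sizes = []
    N = n
    while N >= min_window:
        sizes.append(N)
        N //= 2
    if len(sizes) < 2:
        raise ValueError(
            f"series of length {n} yields fewer than 2 window sizes "
            f"(min_window={min_window})"
        )
    rs_means = []
    for N in sizes:
        k = n // N
        vals = []
        for j in range(k):
            seg = series[j * N : (j + 1) * N]
            try:
                vals.append(rescaled_range(seg))
            except ConstantSegmentError:
                continue  # constant segments carry no R/S information
        if not vals:
            raise ConstantSegmentError(f"all segments constant at window size {N}")
        rs_means.append(float(np.mean(vals)))
    log_n = np.log(np.asarray(sizes, dtype=float))
    log_rs = np.log(np.asarray(rs_means))
    slope, intercept = np.polyfit(log_n, log_rs, 1)
    fitted = slope * log_n + intercept
    sstot = float(np.sum((log_rs - log_rs.mean()) ** 2))
    fit_r2 = 1.0 - float(np.sum((log_rs - fitted) ** 2)) / sstot if sstot > 0 else 1.0
    if fit_r2 < warn_fit_r2:
        warnings.warn(
            f"log-log R/S fit R^2 = {fit_r2:.3f} < {warn_fit_r2}", stacklevel=2
        )
    return HurstResult(
        h=float(slope),
        window_sizes=np.asarray(sizes),
        rs_values=np.asarray(rs_means),
        fit_intercept=float(intercept),
        fit_r2=fit_r2,
    )


def trial_hurst(
    model: SynergyModel | Sequence[np.ndarray],
    min_window: int = 200,
    fundamental_mask: Sequence[bool] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean Hurst exponent over a trial's motor primitives.

    By default every primitive contributes (combined synergies
    included); pass ``fundamental_mask`` to restrict the average.
    Returns ``(trial_mean, per_primitive_h)``.
    """
    primitives = model.P if isinstance(model, SynergyModel) else np.asarray(model)
    hs = np.array([hurst_rs(p, min_window=min_window).h for p in primitives])
    if fundamental_mask is not None:
        mask = np.asarray(fundamental_mask, dtype=bool)
        if mask.shape != hs.shape:
            raise ValueError("mask length must match primitive count")
        hs_used = hs[mask]
    else:
        hs_used = hs
    if hs_used.size == 0:
        raise ValueError("no primitives to average")
    return float(hs_used.mean()), hs
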