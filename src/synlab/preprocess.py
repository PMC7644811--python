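"""EMG envelope computation and gait-cycle normalization.

The processing chain is, in order: zero-phase Butterworth high-pass
(50 Hz) -> full-wave rectification -> zero-phase Butterworth low-pass
(20 Hz, linear envelope) -> per-muscle minimum subtraction and
maximum normalization -> time normalization of each gait cycle to 200
points (100 stance + 100 swing, linear interpolation).

The "4th order zero-phase" filters are realised by designing
2nd-order Butterworth sections and applying them forward-backward
(``sosfiltfilt``), which doubles the effective order - the
conventional reading in movement-science pipelines. The design order
is configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .datatypes import (
    EnvelopeMatrix,
    GaitCycleTimes,
    NormalizedCycles,
    RawEmgRecording,
)


def envelope(
    raw: RawEmgRecording,
    hp_cutoff: float = 50.0,
    lp_cutoff: float = 20.0,
    design_order: int = 2,
) -> EnvelopeMatrix:
    """Linear envelope: high-pass, rectify, low-pass (all zero-phase).

    Each filter is a Butterworth of order ``design_order`` applied
    forward-backward, so the effective order is ``2 * design_order``.
    Residual negative values after low-passing the rectified signal
    are clipped at zero.
    """
    if raw.fs <= 2 * hp_cutoff:
        raise ValueError(f"fs={raw.fs} too low for hp_cutoff={hp_cutoff}")
    if np.any(~np.isfinite(raw.samples)):
        raise ValueError("raw EMG contains NaN or infinite samples")
    sos_hp = signal.butter(design_order, hp_cutoff, btype="highpass", fs=raw.fs, output="sos")
    sos_lp = signal.butter(design_order, lp_cutoff, btype="lowpass", fs=raw.fs, output="sos")
    x = signal.sosfiltfilt(sos_hp, raw.samples, axis=1)
    x = np.abs(x)
    x = signal.sosfiltfilt(sos_lp, x, axis=1)
    return EnvelopeMatrix(values=np.clip(x, 0.0, None), fs=raw.fs, meta=raw.meta)


def normalize_amplitude(env: EnvelopeMatrix) -> EnvelopeMatrix:
    """Per muscle: subtract the trial minimum, divide by the maximum.

    Constant (zero-range) channels map to all-zeros with a warning.
    Idempotent: normalizing twice equals normalizing once.
    """
    v = env.values - env.values.min(axis=1, keepdims=True)
    vmax = v.max(axis=1)
    flat = vmax == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant channel(s) normalized to zero", stacklevel=2
        )
    vmax[flat] = 1.0
    return EnvelopeMatrix(values=v / vmax[:, None], fs=env.fs, meta=env.meta)


def time_normalize(
    env: EnvelopeMatrix,
    events: GaitCycleTimes,
    max_cycles: int = 30,
    points_per_phase: int = 100,
) -> NormalizedCycles:
    """Resample each gait cycle to a fixed number of points.

    The stance phase (touchdown to lift-off) and the swing phase
    (lift-off to next touchdown) are each linearly resampled to
    ``points_per_phase`` points. Phases are half-open: the stance
    samples span [touchdown, lift-off) and the swing samples
    [lift-off, next touchdown). Only the first ``max_cycles`` complete
    cycles are kept.
    """
    n_avail = events.n_cycles
    if n_avail < 2:
        raise ValueError("need at least 2 complete gait cycles")
    n_use = min(max_cycles, n_avail)
    duration = env.values.shape[1] / env.fs
    if events.touchdown[n_use] > duration + 1e-9:
        raise ValueError(
            f"cycle boundary {events.touchdown[n_use]:.3f}s outside "
            f"recording of {duration:.3f}s"
        )
    t_grid = np.arange(env.values.shape[1]) / env.fs
    frac = np.arange(points_per_phase) / points_per_phase
    sample_t = np.empty(2 * points_per_phase * n_use)
    for c in range(n_use):
        td, nxt = events.touchdown[c], events.touchdown[c + 1]
        lo = td + events.stance_duration[c]
        i0 = c * 2 * points_per_phase
        sample_t[i0 : i0 + points_per_phase] = td + (lo - td) * frac
        sample_t[i0 + points_per_phase : i0 + 2 * points_per_phase] = lo + (nxt - lo) * frac
    values = np.stack(
        [np.interp(sample_t, t_grid, env.values[i]) for i in range(env.values.shape[0])]
    )
    return NormalizedCycles(
        values=values, n_cycles=n_use, meta=env.meta, points_per_phase=points_per_phase
    )


def preprocess_trial(
    raw: RawEmgRecording,
    events: GaitCycleTimes,
    hp_cutoff: float = 50.0,
    lp_cutoff: float = 20.0,
    max_cycles: int = 30,
) -> NormalizedCycles:
    """Full chain: envelope -> amplitude normalize -> time normalize."""
    env = envelope(raw, hp_cutoff=hp_cutoff, lp_cutoff=lp_cutoff)
    env = normalize_amplitude(env)
    return time_normalize(env, events, max_cycles=max_cycles)
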