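"""Ground-truth synthetic locomotor EMG.

Generates trials with a known low-rank synergy structure so that every
downstream stage (filtering, normalization, factorization, geometrics,
fractal and statistical analysis) can be validated against truth.

A trial mimics treadmill/overground walking EMG: 13 channels at 2 kHz,
30 gait cycles, envelopes built from four wrapped-Gaussian motor
primitives (weight acceptance, propulsion, early swing, late swing)
mixed through non-negative motor modules, plus truncated-Gaussian
noise. The raw-like signal is a 10-500 Hz band-limited Gaussian
carrier amplitude-modulated by the envelopes.

Also provides exact fractional Gaussian noise (circulant embedding)
used to calibrate the rescaled-range Hurst estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .datatypes import (
    GaitCycleTimes,
    MUSCLES,
    N_MUSCLES,
    POINTS_PER_CYCLE,
    RawEmgRecording,
    TrialMeta,
)

# Canonical module weightings of the four fundamental synergies
# (rows = ME MA FL RF VM VL ST BF TA PL GM GL SO). Dominant muscles:
# knee extensors + hip extensors/abductors (weight acceptance),
# plantarflexors (propulsion), dorsiflexors (early swing), knee
# flexors + dorsiflexors (late swing).
_BASE_MODULES_4 = np.array(
    [
        # WA    PROP   ESW    LSW
        [0.90, 0.10, 0.05, 0.30],   # ME
        [0.80, 0.05, 0.05, 0.25],   # MA
        [0.60, 0.10, 0.30, 0.10],   # FL
        [0.85, 0.10, 0.35, 0.05],   # RF
        [1.00, 0.05, 0.05, 0.10],   # VM
        [0.95, 0.05, 0.05, 0.10],   # VL
        [0.25, 0.10, 0.05, 0.95],   # ST
        [0.30, 0.10, 0.05, 1.00],   # BF
        [0.10, 0.05, 1.00, 0.60],   # TA
        [0.15, 0.80, 0.20, 0.10],   # PL
        [0.10, 1.00, 0.05, 0.15],   # GM
        [0.10, 0.90, 0.05, 0.15],   # GL
        [0.15, 0.95, 0.05, 0.05],   # SO
    ]
)

#: Peak phases (points within the 200-point cycle) and bell widths of
#: the four fundamental primitives: early stance, late stance, early
#: swing, late swing.
_PEAKS_4 = np.array([25.0, 75.0, 125.0, 175.0])
_WIDTH_4 = np.array([12.0, 12.0, 10.0, 12.0])


@dataclass
class GroundTruthSynergies:
    """The generator's hidden low-rank structure."""

    modules_true: np.ndarray      # (13, r), unit-max columns
    primitives_true: np.ndarray   # (r, 200 * n_cycles)
    peak_phases: np.ndarray       # (r,) nominal peak points in [0, 200)
    widths: np.ndarray            # (r,) bell SDs in points
    jitter_sd: float              # per-cycle peak jitter (points)


@dataclass
class SyntheticTrialBundle:
    """One synthetic trial: raw-like EMG, gait events and the truth."""

    raw: RawEmgRecording
    events: GaitCycleTimes
    truth: GroundTruthSynergies
    envelopes: np.ndarray         # (13, 200 * n_cycles), noise applied
    noise_sd: float
    seed: int


def generate_cycle_times(
    n_cycles: int,
    stance_mean: float,
    stance_cv: float,
    cycle_mean: float,
    cycle_cv: float,
    seed: int = 0,
) -> GaitCycleTimes:
    """Draw touchdown times and stance durations with given variability.

    Parameters
    ----------
    n_cycles : number of touchdowns generated (n_cycles - 1 complete
        cycles are usable downstream).
    stance_mean, cycle_mean : mean stance and full-cycle duration (s).
    stance_cv, cycle_cv : step-to-step coefficients of variation (%).
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    if stance_mean <= 0 or cycle_mean <= 0:
        raise ValueError("means must be positive")
    if stance_mean >= cycle_mean:
        raise ValueError("stance_mean must be below cycle_mean")
    rng = np.random.default_rng(seed)
    durations = cycle_mean * (1.0 + cycle_cv / 100.0 * rng.standard_normal(n_cycles - 1))
    durations = np.clip(durations, 0.5 * cycle_mean, 1.5 * cycle_mean)
    touchdown = np.concatenate([[0.0], np.cumsum(durations)])
    stance = stance_mean * (1.0 + stance_cv / 100.0 * rng.standard_normal(n_cycles))
    # keep each stance strictly inside its cycle
    upper = np.concatenate([durations, [cycle_mean]])
    stance = np.clip(stance, 0.05 * stance_mean, 0.95 * upper)
    return GaitCycleTimes(touchdown=touchdown, stance_duration=stance)


def _wrapped_bell(peaks: np.ndarray, width: float) -> np.ndarray:
    """Wrapped-Gaussian bell over one 200-point cycle for each peak."""
    t = np.arange(POINTS_PER_CYCLE)[None, :]
    d = np.abs(t - peaks[:, None])
    d = np.minimum(d, POINTS_PER_CYCLE - d)
    return np.exp(-0.5 * (d / width) ** 2)


def _truth(
    r: int, n_cycles: int, jitter_sd: float, amplitude_cv: float, rng: np.random.Generator
) -> GroundTruthSynergies:
    if r == 4:
        base = _BASE_MODULES_4 * rng.uniform(0.8, 1.2, size=(N_MUSCLES, 4))
        peaks, widths = _PEAKS_4.copy(), _WIDTH_4.copy()
    else:
        base = rng.uniform(0.0, 1.0, size=(N_MUSCLES, r)) ** 2
        peaks = (np.arange(r) + 0.5) * POINTS_PER_CYCLE / r
        widths = np.full(r, 10.0)
    modules = base / base.max(axis=0, keepdims=True)

    prim = np.empty((r, n_cycles * POINTS_PER_CYCLE))
    for c in range(n_cycles):
        jit = peaks + jitter_sd * rng.standard_normal(r)
        amp = np.exp(amplitude_cv * rng.standard_normal(r))
        cycle = amp[:, None] * np.stack(
            [_wrapped_bell(np.array([jit[j]]), widths[j])[0] for j in range(r)]
        )
        prim[:, c * POINTS_PER_CYCLE : (c + 1) * POINTS_PER_CYCLE] = cycle
    return GroundTruthSynergies(
        modules_true=modules,
        primitives_true=prim,
        peak_phases=peaks,
        widths=widths,
        jitter_sd=jitter_sd,
    )


def generate_trial(
    r: int = 4,
    n_cycles: int = 30,
    noise_sd: float = 0.05,
    jitter_sd: float = 2.0,
    seed: int = 0,
    fs: float = 2000.0,
    stance_mean: float = 0.65,
    stance_cv: float = 4.0,
    cycle_mean: float = 1.05,
    cycle_cv: float = 2.0,
    amplitude_cv: float = 0.1,
    meta: Optional[TrialMeta] = None,
) -> SyntheticTrialBundle:
    """Generate one synthetic gait trial with known synergy structure.

    Envelopes are ``modules_true @ primitives_true`` plus Gaussian
    noise of standard deviation ``noise_sd`` (as a fraction of the
    envelope maximum), clipped at zero. The raw-like EMG is a
    band-limited (10-500 Hz) zero-mean carrier modulated by each
    channel's envelope, sampled at ``fs``. Defaults emulate overground
    walking at comfortable speed (cycle ~1.05 s, stance ~0.65 s,
    stance CV ~4%, cadence CV ~2%).
    """
    if not 1 <= r <= 12:
        raise ValueError("r must be in [1, 12]")
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    truth = _truth(r, n_cycles, jitter_sd, amplitude_cv, rng)
    clean = truth.modules_true @ truth.primitives_true
    if noise_sd > 0:
        noise = noise_sd * clean.max() * rng.standard_normal(clean.shape)
        envelopes = np.clip(clean + noise, 0.0, None)
    else:
        envelopes = clean

    # n_cycles + 1 touchdowns so n_cycles complete cycles exist
    events = generate_cycle_times(
        n_cycles + 1, stance_mean, stance_cv, cycle_mean, cycle_cv,
        seed=int(rng.integers(2**31)),
    )

    # map the per-cycle envelope grid onto real time
    env_times = np.empty(n_cycles * POINTS_PER_CYCLE)
    for c in range(n_cycles):
        td, nxt = events.touchdown[c], events.touchdown[c + 1]
        lo = td + events.stance_duration[c]
        i0 = c * POINTS_PER_CYCLE
        env_times[i0 : i0 + 100] = td + (lo - td) * np.arange(100) / 100.0
        env_times[i0 + 100 : i0 + 200] = lo + (nxt - lo) * np.arange(100) / 100.0

    t = np.arange(0.0, events.touchdown[-1], 1.0 / fs)
    sos = signal.butter(2, [10.0, 500.0], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal((N_MUSCLES, t.size)), axis=1)
    carrier /= np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
    env_t = np.stack([np.interp(t, env_times, envelopes[i]) for i in range(N_MUSCLES)])
    raw = RawEmgRecording(samples=carrier * env_t, fs=fs, meta=meta)

    return SyntheticTrialBundle(
        raw=raw, events=events, truth=truth, envelopes=envelopes,
        noise_sd=noise_sd, seed=seed,
    )


def generate_fgn(h_true: float, n: int, seed: int = 0) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Returns a zero-mean, unit-variance series of length ``n`` whose
    autocovariance is that of fGn with Hurst parameter ``h_true``
    (Davies-Harte method; exact, not approximate).
    """
    if not 0.0 < h_true < 1.0:
        raise ValueError("h_true must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * h_true)
        - 2 * np.abs(k) ** (2 * h_true)
        + np.abs(k - 1) ** (2 * h_true)
    )
    # circulant first row of size 2(n-1)
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)  # tiny negatives from roundoff
    m = c.size
    w = np.empty(m, dtype=complex)
    w[0] = rng.standard_normal() * np.sqrt(m)
    w[m // 2] = rng.standard_normal() * np.sqrt(m)
    half = (m - 2) // 2
    z1 = rng.standard_normal(half)
    z2 = rng.standard_normal(half)
    w[1 : half + 1] = (z1 + 1j * z2) * np.sqrt(m / 2.0)
    w[m // 2 + 1 :] = np.conj(w[1 : half + 1][::-1])
    x = np.fft.ifft(np.sqrt(lam) * w)
    return x.real[:n]
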