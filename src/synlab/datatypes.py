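"""Shared data containers for the synergy-analysis pipeline.

All EMG matrices follow a fixed muscle ordering of the 13 recorded
lower-limb muscles (proximal to distal): gluteus medius (ME), gluteus
maximus (MA), tensor fasciae latae (FL), rectus femoris (RF), vastus
medialis (VM), vastus lateralis (VL), semitendinosus (ST), biceps
femoris (BF), tibialis anterior (TA), peroneus longus (PL),
gastrocnemius medialis (GM), gastrocnemius lateralis (GL), soleus (SO).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Canonical muscle ordering used by every matrix in the pipeline.
MUSCLES: tuple[str, ...] = (
    "ME", "MA", "FL", "RF", "VM", "VL", "ST",
    "BF", "TA", "PL", "GM", "GL", "SO",
)

N_MUSCLES = len(MUSCLES)

#: Points per normalized gait cycle (100 stance + 100 swing).
POINTS_PER_CYCLE = 200
POINTS_PER_PHASE = 100

#: Functional labels of the four fundamental locomotor synergies, in
#: order of their peak activity within the normalized gait cycle.
FUNDAMENTAL_LABELS = (
    "weight_acceptance", "propulsion", "early_swing", "late_swing",
)
COMBINED_LABEL = "combined"


@dataclass
class TrialMeta:
    """Participant and condition metadata for one trial."""

    participant: str
    sex: Optional[str] = None            # "M" / "F"
    locomotion: Optional[str] = None     # "W" walking / "R" running
    environment: Optional[str] = None    # "O" overground / "T" treadmill
    speed: Optional[float] = None        # m/s
    age: Optional[float] = None          # years
    height: Optional[float] = None       # cm
    mass: Optional[float] = None         # kg

    def __post_init__(self) -> None:
        if self.locomotion is not None and self.locomotion not in ("W", "R"):
            raise ValueError(f"locomotion must be 'W' or 'R', got {self.locomotion!r}")
        if self.environment is not None and self.environment not in ("O", "T"):
            raise ValueError(f"environment must be 'O' or 'T', got {self.environment!r}")
        if self.speed is not None and self.speed <= 0:
            raise ValueError("speed must be positive")

    @property
    def condition(self) -> str:
        """Two-letter condition code, environment first (e.g. 'OW', 'TR')."""
        return f"{self.environment or '?'}{self.locomotion or '?'}"


@dataclass
class RawEmgRecording:
    """Multi-channel surface EMG sampled at a fixed rate.

    ``samples`` is (13, n_samples) in canonical muscle order.
    """

    samples: np.ndarray
    fs: float = 2000.0
    meta: Optional[TrialMeta] = None
    muscles: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.muscles):
            raise ValueError(
                f"samples must be ({len(self.muscles)}, n); got {self.samples.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GaitCycleTimes:
    """Touchdown times and stance durations of one recorded limb.

    ``touchdown[i]`` is the i-th foot-strike time (s, strictly
    increasing); ``stance_duration[i]`` is the following stance length.
    A *complete* gait cycle requires the next touchdown, so a trial
    with k touchdowns yields k-1 usable cycles.
    """

    touchdown: np.ndarray
    stance_duration: np.ndarray

    def __post_init__(self) -> None:
        self.touchdown = np.asarray(self.touchdown, dtype=float)
        self.stance_duration = np.asarray(self.stance_duration, dtype=float)
        if self.touchdown.shape != self.stance_duration.shape:
            raise ValueError("touchdown and stance_duration must have equal length")
        if self.touchdown.size < 2:
            raise ValueError("need at least 2 touchdowns")
        d = np.diff(self.touchdown)
        if np.any(d <= 0):
            raise ValueError("touchdown times must be strictly increasing")
        if np.any(self.stance_duration[:-1] >= d):
            raise ValueError("stance duration must be shorter than its gait cycle")
        if np.any(self.stance_duration <= 0):
            raise ValueError("stance durations must be positive")

    @property
    def n_cycles(self) -> int:
        """Number of complete touchdown-to-touchdown cycles."""
        return self.touchdown.size - 1

    @property
    def cycle_duration(self) -> np.ndarray:
        return np.diff(self.touchdown)


@dataclass
class EnvelopeMatrix:
    """Non-negative linear envelopes, one row per muscle."""

    values: np.ndarray
    fs: float
    meta: Optional[TrialMeta] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class NormalizedCycles:
    """Amplitude- and time-normalized envelopes.

    (13, 200 * n_cycles); each cycle holds 100 stance then 100 swing
    points; each channel is scaled to [0, 1] per trial.
    """

    values: np.ndarray
    n_cycles: int
    meta: Optional[TrialMeta] = None
    points_per_phase: int = POINTS_PER_PHASE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = 2 * self.points_per_phase * self.n_cycles
        if self.values.shape[1] != expected:
            raise ValueError(
                f"expected {expected} columns for {self.n_cycles} cycles, "
                f"got {self.values.shape[1]}"
            )

    @property
    def points_per_cycle(self) -> int:
        return 2 * self.points_per_phase


@dataclass
class SynergyModel:
    """One NMF factorization V ~ M @ P.

    M (m x r) holds the motor modules (muscle weightings), P (r x n)
    the motor primitives (time-dependent coefficients).
    """

    M: np.ndarray
    P: np.ndarray
    r: int
    r2: float
    iterations: int
    seed: int
    r2_history: Optional[np.ndarray] = None

    @property
    def n_cycles(self) -> int:
        return self.P.shape[1] // POINTS_PER_CYCLE

    def normalized(self) -> "SynergyModel":
        """Resolve scale ambiguity: unit-max module columns, primitives
        scaled inversely so the product M @ P is unchanged."""
        scale = self.M.max(axis=0)
        scale[scale == 0] = 1.0
        return SynergyModel(
            M=self.M / scale,
            P=self.P * scale[:, None],
            r=self.r,
            r2=self.r2,
            iterations=self.iterations,
            seed=self.seed,
            r2_history=self.r2_history,
        )


@dataclass
class RankCurve:
    """Best-of-restarts reconstruction R^2 for each candidate rank."""

    ranks: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.r2 = np.asarray(self.r2, dtype=float)
        if self.ranks.shape != self.r2.shape:
            raise ValueError("ranks and r2 must align")


@dataclass
class SynergyLabel:
    """Functional classification of one extracted synergy."""

    label: str
    shape_index: Optional[int]
    match_weight: float
    match_r2: float

    @property
    def is_fundamental(self) -> bool:
        return self.label != COMBINED_LABEL


@dataclass
class PrincipalShapes:
    """Mean-cycle reference curves obtained by clustering primitives."""

    shapes: np.ndarray              # (k, 200), non-negative, unit max
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        if self.shapes.ndim != 2 or self.shapes.shape[0] < 2:
            raise ValueError("need at least 2 shapes of equal length")


@dataclass
class HurstResult:
    """Rescaled-range Hurst estimate with its log-log fit diagnostics."""

    h: float
    window_sizes: np.ndarray
    rs_values: np.ndarray
    fit_intercept: float
    fit_r2: float


@dataclass
class GaitSummary:
    """Spatiotemporal gait parameters and their step-to-step variability."""

    stance_mean: float      # s
    swing_mean: float       # s
    cadence_mean: float     # steps/min
    stance_cv: float        # %
    swing_cv: float         # %
    cadence_cv: float       # %
    n_cycles: int = 0
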