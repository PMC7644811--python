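"""Spatiotemporal gait parameters and their step-to-step variability.

From touchdown times and stance durations of one limb: per-cycle
stance, swing (cycle duration minus stance) and cadence. Cadence
assumes symmetric stepping, so one limb's gait cycle of duration d
contains two steps: cadence = 120 / d steps per minute. Variability
is the percent coefficient of variation (100 * sd / mean, sample sd)
of each per-cycle series. The last touchdown has no following cycle
and is dropped from the duration-based series.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GaitCycleTimes, GaitSummary, TrialMeta


def _cv(x: np.ndarray) -> float:
    return float(100.0 * x.std(ddof=1) / x.mean())


def gait_summary(events: GaitCycleTimes) -> GaitSummary:
    """Means and CVs of stance, swing and cadence for one trial."""
    durations = events.cycle_duration
    if durations.size < 2:
        raise ValueError("need at least 2 complete cycles")
    stance = events.stance_duration[: durations.size]
    swing = durations - stance
    if np.any(swing <= 0):
        raise ValueError("stance must be shorter than its cycle")
    cadence = 120.0 / durations
    return GaitSummary(
        stance_mean=float(stance.mean()),
        swing_mean=float(swing.mean()),
        cadence_mean=float(cadence.mean()),
        stance_cv=_cv(stance),
        swing_cv=_cv(swing),
        cadence_cv=_cv(cadence),
        n_cycles=int(durations.size),
    )


def summary_table(
    trials: Sequence[tuple[TrialMeta, GaitCycleTimes]]
) -> pd.DataFrame:
    """Tidy per-trial table of gait parameters with condition columns."""
    rows = []
    for meta, events in trials:
        s = gait_summary(events)
        rows.append(
            {
                "participant": meta.participant,
                "locomotion": meta.locomotion,
                "environment": meta.environment,
                "stance_mean": s.stance_mean,
                "swing_mean": s.swing_mean,
                "cadence_mean": s.cadence_mean,
                "stance_cv": s.stance_cv,
                "swing_cv": s.swing_cv,
                "cadence_cv": s.cadence_cv,
                "n_cycles": s.n_cycles,
            }
        )
    return pd.DataFrame(rows)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of the CV columns per locomotion condition."""
    cols = ["stance_cv", "swing_cv", "cadence_cv"]
    g = table.groupby(["locomotion", "environment"])[cols]
    out = g.agg(["mean", "std"])
    out.columns = [f"{c}_{stat}" for c, stat in out.columns]
    return out.reset_index()
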