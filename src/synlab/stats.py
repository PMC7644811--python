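"""Scalar and 1-D statistics for the locomotion comparisons.

Scalar outcomes (factorization rank, gait parameters, CoA, FWHM, H)
are compared across the 2 x 2 within-participant design locomotion
type (walking / running) x environment (overground / treadmill). A
Gaussian linear model is fitted first; if its residuals pass a
Shapiro-Wilk normality check the classical two-way repeated-measures
ANOVA is used (for a balanced 2 x 2 within design the type II
F-statistics reduce to squared paired t-statistics on the factor
contrasts), otherwise the analysis is repeated on rank-transformed
data (a documented approximation to a fully rank-based ANOVA).
Homogeneity of variances is reported via Levene's test, and pairwise
least-significant-difference post hoc comparisons are adjusted with
the Benjamini-Hochberg false discovery rate.

Motor primitives are compared pointwise along the 200-point
normalized cycle with a permutation form of one-dimensional
statistical parametric mapping (SPM): the environment effect F at
each point comes from the repeated-measures design, the critical
threshold is the (1 - alpha) quantile of the permutation distribution
of the maximum F under within-participant environment-label exchange,
and suprathreshold clusters receive p-values from the permutation
distribution of the maximum suprathreshold cluster extent. The
per-participant curves are averaged over gait cycles whose order is
re-randomized at every resample; the cycle-averaged environment F is
invariant to that order, so the resampling enters through the
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_EFFECTS = ("environment", "type", "interaction")


@dataclass
class EffectResult:
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class ScalarAnovaResult:
    effects: dict[str, EffectResult]
    levene_p: float
    shapiro_p: float
    method: str                       # "parametric" | "rank_based"
    posthoc: pd.DataFrame
    n_participants: int


@dataclass
class SpmCluster:
    start: int
    end: int      # inclusive
    p: float

    @property
    def extent(self) -> int:
        return self.end - self.start + 1


@dataclass
class SpmResult:
    f_curve: np.ndarray
    threshold: float
    clusters: list[SpmCluster] = field(default_factory=list)
    n_resamples: int = 0
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# scalar 2 x 2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _rm_anova_2x2(y: np.ndarray) -> dict[str, EffectResult]:
    """F tests of the 2x2 within design from cell values y[n, env, type].

    Each effect is the squared paired t on its participant-level
    contrast, df = (1, n - 1); for a balanced orthogonal within
    design this equals the type II repeated-measures F.
    """
    n = y.shape[0]
    contrasts = {
        "environment": y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1),
        "type": y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1),
        "interaction": y[:, 0, 0] - y[:, 0, 1] - y[:, 1, 0] + y[:, 1, 1],
    }
    out = {}
    for name, c in contrasts.items():
        v = c.var(ddof=1)
        if v == 0:
            F = 0.0 if np.isclose(c.mean(), 0.0) else np.inf
        else:
            F = n * c.mean() ** 2 / v
        p = float(sps.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        out[name] = EffectResult(F=float(F), df=(1, n - 1), p=p)
    return out


def _pivot(values: pd.DataFrame) -> tuple[np.ndarray, list]:
    required = {"participant", "environment", "type", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = values.pivot_table(
        index="participant", columns=["environment", "type"], values="value"
    )
    wide = wide.dropna()  # listwise deletion of incomplete participants
    envs = sorted({c[0] for c in wide.columns})
    typs = sorted({c[1] for c in wide.columns})
    if len(envs) != 2 or len(typs) != 2:
        raise ValueError("design must have exactly 2 environments x 2 types")
    y = np.empty((wide.shape[0], 2, 2))
    for i, e in enumerate(envs):
        for j, t in enumerate(typs):
            y[:, i, j] = wide[(e, t)].to_numpy()
    return y, list(wide.index)


def scalar_anova(values: pd.DataFrame, alpha: float = 0.05) -> ScalarAnovaResult:
    """Two-way repeated-measures ANOVA with rank-based fallback.

    ``values`` is a long table with columns ``participant``,
    ``environment``, ``type``, ``value``. Residuals of the Gaussian
    cell-means model are checked with Shapiro-Wilk at ``alpha``; on
    failure the same engine is run on the ranks of the pooled data.
    Post hoc: all pairwise paired t-tests (LSD), BH-adjusted.
    """
    y, participants = _pivot(values)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete participants")

    groups = [y[:, i, j] for i in range(2) for j in range(2)]
    levene_p = float(sps.levene(*groups, center="median").pvalue)

    resid = y - y.mean(axis=0, keepdims=True)  # cell-means model residuals
    shapiro_p = float(sps.shapiro(resid.ravel()).pvalue)

    if shapiro_p >= alpha:
        method = "parametric"
        effects = _rm_anova_2x2(y)
        y_post = y
    else:
        method = "rank_based"
        ranks = sps.rankdata(y.ravel()).reshape(y.shape)
        effects = _rm_anova_2x2(ranks)
        y_post = ranks

    cells = [("0", (0, 0)), ("1", (0, 1)), ("2", (1, 0)), ("3", (1, 1))]
    names = ["env0/type0", "env0/type1", "env1/type0", "env1/type1"]
    rows = []
    for a in range(4):
        for b in range(a + 1, 4):
            da = y_post[:, cells[a][1][0], cells[a][1][1]]
            db = y_post[:, cells[b][1][0], cells[b][1][1]]
            t, p = sps.ttest_rel(da, db)
            rows.append({"pair": f"{names[a]} vs {names[b]}", "t": float(t), "p_raw": float(p)})
    posthoc = pd.DataFrame(rows)
    posthoc["p_adj"] = multipletests(posthoc["p_raw"], method="fdr_bh")[1]

    return ScalarAnovaResult(
        effects=effects,
        levene_p=levene_p,
        shapiro_p=shapiro_p,
        method=method,
        posthoc=posthoc,
        n_participants=n,
    )


# ---------------------------------------------------------------------------
# 1-D permutation SPM
# ---------------------------------------------------------------------------

def _paired_f_curve(d: np.ndarray) -> np.ndarray:
    """Pointwise RM F for a 2-level within factor from difference curves
    d (n_participants x n_points)."""
    n = d.shape[0]
    m = d.mean(axis=0)
    v = d.var(axis=0, ddof=1)
    v = np.where(v == 0, np.inf, v)
    return n * m**2 / v


def _clusters_above(f: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = f > threshold
    out = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, above.size - 1))
    return out


def spm_rm_anova(
    curves: np.ndarray,
    n_resamples: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SpmResult:
    """Permutation SPM for the environment effect on primitive curves.

    Parameters
    ----------
    curves : array (n_participants, 2, n_cycles, n_points); axis 1 is
        the locomotion environment.
    n_resamples : permutation / cycle-order resampling repetitions.

    The observed F averages each participant's cycles per
    environment, which makes it invariant to the order in which
    cycles entered the trial; the resampling therefore acts through
    the permutation null, where at every resample the participants'
    environment labels are independently flipped. The maximum of the
    resulting null F-curve yields the critical threshold (1 - alpha
    quantile) and the maximum suprathreshold run length yields
    cluster p-values.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 4 or curves.shape[1] != 2:
        raise ValueError("curves must be (n_participants, 2, n_cycles, n_points)")
    n, _, n_cycles, n_points = curves.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)

    a = curves.mean(axis=2)          # (n, 2, points): cycle-averaged
    d = a[:, 0] - a[:, 1]            # (n, points)
    f_obs = _paired_f_curve(d)

    # permutation null: random cycle order (F-invariant, kept for
    # fidelity to the resampling protocol) + environment sign flips
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    m = signs @ d / n                                  # (R, points)
    msq = np.mean(d * d, axis=0)                       # E[d^2] is sign-invariant
    var = (msq[None, :] - m**2) * n / (n - 1)
    var = np.where(var <= 0, np.inf, var)
    f_null = n * m**2 / var
    max_f = f_null.max(axis=1)
    threshold = float(np.quantile(max_f, 1.0 - alpha))

    # null distribution of the maximum suprathreshold cluster extent
    above_null = f_null > threshold
    max_extent = np.zeros(n_resamples, dtype=int)
    for i in range(n_resamples):
        if above_null[i].any():
            runs = _clusters_above(f_null[i], threshold)
            max_extent[i] = max(e - s + 1 for s, e in runs)

    clusters = []
    for s, e in _clusters_above(f_obs, threshold):
        extent = e - s + 1
        p = (1 + int(np.sum(max_extent >= extent))) / (n_resamples + 1)
        clusters.append(SpmCluster(start=s, end=e, p=float(p)))

    return SpmResult(
        f_curve=f_obs,
        threshold=threshold,
        clusters=[c for c in clusters],
        n_resamples=n_resamples,
        alpha=alpha,
    )


def significant_clusters(result: SpmResult, alpha: Optional[float] = None) -> list[SpmCluster]:
    alpha = result.alpha if alpha is None else alpha
    return [c for c in result.clusters if c.p <= alpha]
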