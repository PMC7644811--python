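"""Functional classification of extracted synergies.

Motor primitives from many trials of one locomotion condition are
clustered by factorizing the stacked mean-cycle curves with the same
NMF engine used for synergy extraction, with the number of clusters
set to the maximum factorization rank plus one. The resulting
"principal shapes" are reference activation curves; a primitive is
assigned to the shape carrying its largest clustering weight,
provided that weight reaches the mean of all weights, and confirmed
as *fundamental* if its R^2 against the assigned shape reaches 25% of
the average R^2 of the remaining assigned primitives against their
own shapes (four times that average when it is negative). Primitives
failing either gate are *combined* (blends or splits of fundamentals).

Fundamental shapes are named by where their single main peak falls in
the normalized cycle: early stance -> weight acceptance, late stance
-> propulsion, early swing -> early swing, late swing -> late swing.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    COMBINED_LABEL,
    FUNDAMENTAL_LABELS,
    POINTS_PER_CYCLE,
    PrincipalShapes,
    SynergyLabel,
    SynergyModel,
)
from .nmf import nmf_factorize

#: Peak-location windows (in normalized-cycle points) used to name
#: fundamental shapes; boundaries at quarter-cycle marks.
DEFAULT_WINDOWS = {
    "weight_acceptance": (0, 50),
    "propulsion": (50, 100),
    "early_swing": (100, 150),
    "late_swing": (150, 200),
}


def mean_cycle(primitive: np.ndarray, points_per_cycle: int = POINTS_PER_CYCLE) -> np.ndarray:
    """Average a full-trial primitive over its gait cycles."""
    primitive = np.asarray(primitive, dtype=float)
    if primitive.size % points_per_cycle:
        raise ValueError("primitive length is not a whole number of cycles")
    return primitive.reshape(-1, points_per_cycle).mean(axis=0)


def assign_function(
    shapes: PrincipalShapes, windows: Optional[dict] = None
) -> list[str]:
    """Name each principal shape by its peak location in the cycle."""
    windows = windows or DEFAULT_WINDOWS
    labels: list[str] = []
    for shape in shapes.shapes:
        peak = int(np.argmax(shape))
        name = COMBINED_LABEL
        for label, (lo, hi) in windows.items():
            if lo <= peak < hi:
                name = label
                break
        labels.append(name)
    dup = {l for l in labels if labels.count(l) > 1 and l != COMBINED_LABEL}
    if dup:
        warnings.warn(f"multiple shapes share the label(s): {sorted(dup)}", stacklevel=2)
    shapes.labels = labels
    return labels


def _curve_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def cluster_primitives(
    primitives: Sequence[np.ndarray],
    max_rank: int,
    seed: int = 0,
    n_restarts: int = 10,
    r2_fraction: float = 0.25,
    windows: Optional[dict] = None,
) -> tuple[PrincipalShapes, list[SynergyLabel]]:
    """Cluster mean-cycle primitives into principal shapes and label them.

    Parameters
    ----------
    primitives : per-synergy mean-cycle curves (each 200 points),
        pooled across the trials of one locomotion condition.
    max_rank : maximum factorization rank among the pooled trials;
        the number of clusters is ``max_rank + 1``.
    """
    G = np.asarray([np.asarray(p, dtype=float) for p in primitives])
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need at least 2 primitives of equal length")
    k = max_rank + 1

    best = None
    for j in range(n_restarts):
        mdl = nmf_factorize(G, k, seed=seed + j)
        if best is None or mdl.r2 > best.r2:
            best = mdl
    W, S = best.M, best.P  # weights (n_prim x k), shapes (k x 200)

    # resolve scale ambiguity: unit-max shapes, weights scaled inversely
    smax = S.max(axis=1)
    smax[smax == 0] = 1.0
    S = S / smax[:, None]
    W = W * smax[None, :]

    shapes = PrincipalShapes(shapes=S)
    shape_labels = assign_function(shapes, windows=windows)

    w_mean = float(W.mean())
    assigned = np.argmax(W, axis=1)
    provisional = W[np.arange(G.shape[0]), assigned] >= w_mean
    r2 = np.array(
        [
            _curve_r2(G[i], W[i, assigned[i]] * S[assigned[i]])
            for i in range(G.shape[0])
        ]
    )

    labels: list[SynergyLabel] = []
    for i in range(G.shape[0]):
        weight = float(W[i, assigned[i]])
        if not provisional[i]:
            labels.append(SynergyLabel(COMBINED_LABEL, None, weight, float(r2[i])))
            continue
        others = provisional.copy()
        others[i] = False
        ref = float(r2[others].mean()) if np.any(others) else 0.0
        threshold = r2_fraction * ref if ref >= 0 else 4.0 * ref
        if r2[i] >= threshold:
            labels.append(
                SynergyLabel(shape_labels[assigned[i]], int(assigned[i]), weight, float(r2[i]))
            )
        else:
            labels.append(SynergyLabel(COMBINED_LABEL, None, weight, float(r2[i])))
    return shapes, labels


def classify_models(
    models: Sequence[SynergyModel],
    seed: int = 0,
    **kwargs,
) -> tuple[PrincipalShapes, list[list[SynergyLabel]]]:
    """Classify every synergy of a set of per-trial models.

    Pools the mean-cycle primitives of all trials (one locomotion
    condition), clusters them, and regroups the labels per trial.
    """
    curves, owner = [], []
    for t, mdl in enumerate(models):
        norm = mdl.normalized()
        for j in range(norm.r):
            curves.append(mean_cycle(norm.P[j]))
            owner.append(t)
    max_rank = max(mdl.r for mdl in models)
    shapes, flat = cluster_primitives(curves, max_rank=max_rank, seed=seed, **kwargs)
    per_trial: list[list[SynergyLabel]] = [[] for _ in models]
    for lab, t in zip(flat, owner):
        per_trial[t].append(lab)
    return shapes, per_trial


def combined_fraction(labels: Sequence[SynergyLabel]) -> float:
    """Fraction of synergies labeled combined, in [0, 1]."""
    labels = list(labels)
    if not labels:
        return 0.0
    return sum(not l.is_fundamental for l in labels) / len(labels)
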