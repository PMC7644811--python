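"""Muscle-synergy extraction by non-negative matrix factorization.

The envelope matrix V (muscles x time) is factorized as V ~ M @ P
with multiplicative updates minimizing the Frobenius reconstruction
error (Lee-Seung): each iteration updates the motor primitives P,

    P <- P * (M^T V) / (M^T M P),

then the motor modules M,

    M <- M * (V P^T) / (M P P^T),

elementwise with an epsilon guard in the denominators. Reconstruction
quality is tracked each iteration as the coefficient of determination
R^2 = 1 - ||V - MP||^2 / ||V - mean(V)||^2 and the loop stops when
the relative R^2 change over a 20-iteration window drops below 0.01%.

The factorization rank is chosen from the best-of-restarts R^2 versus
rank curve: starting from all candidate ranks, an ordinary least
squares line is fitted; while its mean squared error is above 1e-4
the lowest rank is dropped and the fit repeated; the first rank of
the first sufficiently linear tail is returned.
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

import numpy as np

from .datatypes import NormalizedCycles, RankCurve, SynergyModel

_EPS = 1e-12
_WINDOW = 20


def _as_matrix(V: Union[np.ndarray, NormalizedCycles]) -> np.ndarray:
    if isinstance(V, NormalizedCycles):
        V = V.values
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    if not np.any(V > 0):
        raise ValueError("V must not be all zero")
    return V


def nmf_factorize(
    V: Union[np.ndarray, NormalizedCycles],
    r: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-4,
    eps: float = _EPS,
    relative_tol: bool = True,
    keep_history: bool = False,
) -> SynergyModel:
    """Factorize V into ``r`` synergies with multiplicative updates.

    ``tol`` is the convergence bound on the R^2 change over the last
    20 iterations (relative change by default, absolute when
    ``relative_tol`` is False). M and P are initialized i.i.d.
    uniform on (0, 1].
    """
    V = _as_matrix(V)
    m, n = V.shape
    if not 1 <= r <= min(m, n):
        raise ValueError(f"rank {r} out of range for a {m}x{n} matrix")

    rng = np.random.default_rng(seed)
    M = 1.0 - rng.random((m, r))
    P = 1.0 - rng.random((r, n))

    vsq = float(np.sum(V * V))
    sstot = float(np.sum((V - V.mean()) ** 2))
    history = np.empty(max_iter)
    r2 = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # update primitives
        MtV = M.T @ V
        MtM = M.T @ M
        P *= MtV / (MtM @ P + eps)
        # update modules
        VPt = V @ P.T
        PPt = P @ P.T
        M *= VPt / (M @ PPt + eps)
        # R^2 from small Gram products: ||V-MP||^2 =
        # ||V||^2 - 2<M, V P^T> + tr((M^T M)(P P^T))
        cross = float(np.sum(M * VPt))
        quad = float(np.sum((M.T @ M) * PPt))
        r2 = 1.0 - (vsq - 2.0 * cross + quad) / sstot
        history[it - 1] = r2
        if it > _WINDOW:
            prev = history[it - 1 - _WINDOW]
            delta = r2 - prev
            if relative_tol:
                if prev > 0 and delta / prev < tol:
                    break
            elif delta < tol:
                break

    return SynergyModel(
        M=M, P=P, r=r, r2=float(r2), iterations=it, seed=seed,
        r2_history=history[:it].copy() if keep_history else None,
    )


def _restart_seed(master_seed: int, rank: int, restart: int) -> int:
    return int(master_seed) + rank * 100 + restart


def extract_synergies(
    V: Union[np.ndarray, NormalizedCycles],
    n_restarts: int = 10,
    ranks: Iterable[int] = range(1, 11),
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-4,
) -> tuple[RankCurve, dict[int, SynergyModel]]:
    """Run the factorization over candidate ranks with random restarts.

    For each rank the factorization is repeated ``n_restarts`` times
    from fresh random initializations (seeds derived deterministically
    from ``seed``) and the solution with the highest R^2 is kept.
    """
    ranks = list(ranks)
    best: dict[int, SynergyModel] = {}
    for r in ranks:
        models = [
            nmf_factorize(V, r, seed=_restart_seed(seed, r, j), max_iter=max_iter, tol=tol)
            for j in range(n_restarts)
        ]
        best[r] = max(models, key=lambda mdl: mdl.r2)
    curve = RankCurve(ranks=np.array(ranks), r2=np.array([best[r].r2 for r in ranks]))
    return curve, best


def select_rank(curve: RankCurve, mse_threshold: float = 1e-4) -> int:
    """Choose the factorization rank from the R^2-vs-rank curve.

    Fit a least-squares line to the current curve; if its mean squared
    error is below ``mse_threshold`` return the first rank of the
    curve, otherwise drop the first point and repeat. When only two
    points remain the first of them is returned (a line through two
    points is exact).
    """
    ranks = np.asarray(curve.ranks, dtype=float)
    r2 = np.asarray(curve.r2, dtype=float)
    if ranks.size < 2:
        raise ValueError("rank curve needs at least 2 points")
    start = 0
    while ranks.size - start > 2:
        x, y = ranks[start:], r2[start:]
        slope, intercept = np.polyfit(x, y, 1)
        mse = float(np.mean((y - (slope * x + intercept)) ** 2))
        if mse < mse_threshold:
            return int(ranks[start])
        start += 1
    return int(ranks[start])


def match_modules(
    M_est: np.ndarray, M_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy column matching on cosine similarity.

    Pairs each true module column with the most similar unmatched
    estimated column. Returns (permutation, similarities) where
    ``permutation[j]`` is the estimated column matched to true column
    j.
    """
    def _unit(A: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        return A / norms

    sim = _unit(M_true).T @ _unit(M_est)  # (r_true, r_est)
    perm = np.full(M_true.shape[1], -1)
    sims = np.zeros(M_true.shape[1])
    avail = set(range(M_est.shape[1]))
    order = np.argsort(-sim.max(axis=1))
    for j in order:
        cols = sorted(avail, key=lambda c: -sim[j, c])
        if cols:
            perm[j] = cols[0]
            sims[j] = sim[j, cols[0]]
            avail.discard(cols[0])
    return perm, sims
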