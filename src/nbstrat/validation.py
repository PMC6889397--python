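"""Cluster validity indices and model selection for the cluster count.

Three internal indices are computed on the feature-space distances induced by
the final composite kernel — the space the clustering actually optimizes:

* mean silhouette ``(b_i - a_i) / max(a_i, b_i)`` (maximize),
* the Dunn index, minimum between-cluster distance over maximum
  within-cluster diameter (maximize), and
* connectivity, which penalizes samples whose nearest neighbors fall in a
  different cluster (minimize).

Per candidate ``k`` the three index rankings are combined by weighted
Spearman-footrule rank aggregation (exact enumeration; candidate lists are
small), and the winning ``k`` is recorded per restart.  The final choice is
the mode over restarts, ties broken toward the smaller, more parsimonious k.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .exceptions import ParameterError, UndefinedIndexError
from .kernels import KernelBank, kernel_distance
from .mvkkm import MVKKMConfig, mvkkm_fit, _composite_values

__all__ = [
    "ValidityScores",
    "KSelectionReport",
    "mean_silhouette",
    "silhouette_samples",
    "dunn_index",
    "connectivity",
    "rank_aggregate",
    "select_k",
    "select_p",
]


@dataclass
class ValidityScores:
    k: int
    silhouette: float
    dunn: float
    connectivity: float
    a: np.ndarray | None = None  # per-sample mean intra-cluster distance
    b: np.ndarray | None = None  # per-sample mean nearest-other-cluster distance


@dataclass
class KSelectionReport:
    per_restart_choices: list[int]
    final_k: int
    per_k_scores: dict[int, ValidityScores]
    aggregated_ranking: list[int]


def _group_means(dist: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean distance from each sample to each cluster; returns (M, clusters, counts)."""
    clusters = np.unique(labels)
    Z = (labels[:, None] == clusters[None, :]).astype(float)
    counts = Z.sum(axis=0)
    M = dist @ Z / counts[None, :]
    return M, clusters, counts


def silhouette_samples(dist: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample silhouette values plus the (a_i, b_i) components.

    ``a_i`` is the mean distance to the other members of i's cluster (0 for a
    singleton, whose silhouette is 0 by convention); ``b_i`` the smallest mean
    distance to another cluster.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedIndexError("silhouette needs at least two clusters")
    M, clusters, counts = _group_means(dist, labels)
    own_col = np.searchsorted(clusters, labels)
    n = len(labels)
    own_count = counts[own_col]
    # exclude self from the own-cluster mean (singletons get a = 0)
    a = np.zeros(n)
    multi = own_count > 1
    a[multi] = (
        M[np.arange(n), own_col][multi] * own_count[multi] / (own_count[multi] - 1)
    )
    M_other = M.copy()
    M_other[np.arange(n), own_col] = np.inf
    b = M_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where((own_count > 1) & (denom > 0), (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return s, a, b


def mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    s, _, _ = silhouette_samples(dist, labels)
    return float(s.mean())


def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance / max within-cluster diameter.

    A zero maximum diameter (all clusters are points) yields ``inf``.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise UndefinedIndexError("Dunn index needs at least two clusters")
    idx = [np.flatnonzero(labels == c) for c in clusters]
    diam = 0.0
    for i in idx:
        if i.size > 1:
            diam = max(diam, float(dist[np.ix_(i, i)].max()))
    sep = np.inf
    for (ia, ib) in itertools.combinations(idx, 2):
        sep = min(sep, float(dist[np.ix_(ia, ib)].min()))
    if diam == 0.0:
        return np.inf
    return sep / diam


def connectivity(dist: np.ndarray, labels: np.ndarray, L: int = 10) -> float:
    """Sum over samples of ``1/j`` for each of the L nearest neighbors ``j``
    that lies in a different cluster; 0 iff all neighborhoods are pure."""
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = dist.shape[0]
    if L <= 0:
        raise ParameterError("neighbor count L must be positive")
    if L >= n:
        raise ParameterError("L must be smaller than the sample count")
    # stable argsort so equidistant neighbors resolve by index, deterministically
    order = np.argsort(dist, axis=1, kind="stable")
    total = 0.0
    inv = 1.0 / np.arange(1, L + 1)
    for i in range(n):
        neigh = order[i][order[i] != i][:L]
        total += float(inv[labels[neigh] != labels[i]].sum())
    return total


def rank_aggregate(
    rankings: Sequence[Sequence], importance: Sequence[float] | None = None
) -> list:
    """Consensus ordering minimizing the weighted Spearman footrule distance.

    Exact enumeration over all permutations of the candidate set (bounded at
    8 candidates); among minimizers the first in lexicographic order of the
    sorted candidates wins, i.e. ties break toward smaller candidates earlier.
    """
    if not rankings:
        raise ParameterError("need at least one ranking")
    candidates = sorted(rankings[0])
    for r in rankings:
        if sorted(r) != candidates:
            raise ParameterError("all rankings must permute the same candidate set")
    if len(candidates) > 8:
        raise ParameterError("rank aggregation is enumerated; at most 8 candidates")
    if importance is None:
        importance = [1.0] * len(rankings)
    if len(importance) != len(rankings):
        raise ParameterError("one importance weight per ranking")
    positions = [{c: i for i, c in enumerate(r)} for r in rankings]
    best_perm: tuple | None = None
    best_cost = np.inf
    for perm in itertools.permutations(candidates):
        cost = 0.0
        for pos, w in zip(positions, importance):
            cost += w * sum(abs(i - pos[c]) for i, c in enumerate(perm))
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_perm = perm
    assert best_perm is not None
    return list(best_perm)


def _score_partition(dist: np.ndarray, labels: np.ndarray, k: int, L: int) -> ValidityScores:
    s, a, b = silhouette_samples(dist, labels)
    return ValidityScores(
        k=k,
        silhouette=float(s.mean()),
        dunn=dunn_index(dist, labels),
        connectivity=connectivity(dist, labels, L=min(L, dist.shape[0] - 1)),
        a=a,
        b=b,
    )


def _rank_by(k_range: Sequence[int], scores: dict[int, float], maximize: bool) -> list[int]:
    sign = -1.0 if maximize else 1.0
    return sorted(k_range, key=lambda k: (sign * scores[k], k))


def select_k(
    bank: KernelBank,
    p: float,
    k_range: Sequence[int],
    config: MVKKMConfig,
    *,
    importance: Sequence[float] = (1.0, 1.0, 1.0),
    neighbor_count: int = 10,
) -> KSelectionReport:
    """Choose the cluster count by aggregated validity indices over restarts.

    Per restart, MVKKM is fitted once for every candidate k; silhouette, Dunn
    and connectivity are scored on the fitted composite-kernel distances, the
    three per-index rankings are footrule-aggregated, and the top candidate is
    recorded.  The final k is the mode over restarts (ties to the smaller k).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ParameterError("empty k_range")
    n = bank.n_samples
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ParameterError("k_range must lie within [2, n-1]")
    stacked = bank.stacked()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    choices: list[int] = []
    score_sums: dict[int, np.ndarray] = {k: np.zeros(3) for k in k_range}
    for ss in seeds:
        restart_seed = int(ss.generate_state(1)[0] % (2**31))
        sil: dict[int, float] = {}
        dun: dict[int, float] = {}
        con: dict[int, float] = {}
        for k in k_range:
            cfg = dc_replace(config, k=k, n_restarts=1, seed=restart_seed)
            fit = mvkkm_fit(bank, cfg)
            dist = kernel_distance(_composite_values(stacked, fit.weights, p))
            sc = _score_partition(dist, fit.labels, k, neighbor_count)
            sil[k], dun[k], con[k] = sc.silhouette, sc.dunn, sc.connectivity
            score_sums[k] += np.array([sc.silhouette, sc.dunn, sc.connectivity])
        rankings = [
            _rank_by(k_range, sil, maximize=True),
            _rank_by(k_range, dun, maximize=True),
            _rank_by(k_range, con, maximize=False),
        ]
        choices.append(rank_aggregate(rankings, importance)[0])
    counts = Counter(choices)
    top = max(counts.values())
    final_k = min(k for k, c in counts.items() if c == top)

    mean_scores = {
        k: ValidityScores(
            k=k,
            silhouette=float(score_sums[k][0] / config.n_restarts),
            dunn=float(score_sums[k][1] / config.n_restarts),
            connectivity=float(score_sums[k][2] / config.n_restarts),
        )
        for k in k_range
    }
    agg = rank_aggregate(
        [
            _rank_by(k_range, {k: v.silhouette for k, v in mean_scores.items()}, True),
            _rank_by(k_range, {k: v.dunn for k, v in mean_scores.items()}, True),
            _rank_by(k_range, {k: v.connectivity for k, v in mean_scores.items()}, False),
        ],
        importance,
    )
    return KSelectionReport(
        per_restart_choices=choices,
        final_k=final_k,
        per_k_scores=mean_scores,
        aggregated_ranking=agg,
    )


def select_p(
    bank: KernelBank,
    p_grid: Sequence[float],
    k: int,
    config: MVKKMConfig,
) -> tuple[float, dict[float, float]]:
    """Pick the sparsity exponent maximizing mean silhouette at fixed k.

    Returns the winning p (ties toward the smaller value) together with the
    per-p mean-silhouette table.
    """
    if len(p_grid) == 0:
        raise ParameterError("empty p grid")
    stacked = bank.stacked()
    scores: dict[float, float] = {}
    for p in sorted(p_grid):
        cfg = dc_replace(config, k=k, p=float(p))
        fit = mvkkm_fit(bank, cfg)
        dist = kernel_distance(_composite_values(stacked, fit.weights, float(p)))
        scores[float(p)] = mean_silhouette(dist, fit.labels)
    best = min(scores, key=lambda p: (-scores[p], p))
    return best, scores
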