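"""Multi-view kernel k-means (MVKKM).

The algorithm alternates two steps on a bank of Gram matrices:

1. kernel k-means assignment on the current composite kernel
   ``K~ = sum_v w_v^p K^(v)`` until the labels stabilize, and
2. a closed-form re-weighting of the kernels by inverse within-cluster
   distortion, ``w_v  proportional to  D_v^(-1/(p-1))``,

which is the KKT minimizer of the composite distortion ``sum_v w_v^p D_v``
over the weight simplex for fixed labels.  The per-kernel distortion is the
within-cluster scatter in that kernel's feature space,

    D_v = sum_c [ sum_{i in c} K_ii - (1/|c|) sum_{i,j in c} K_ij ].

Both steps decrease the composite distortion, so the objective trace is
non-increasing.  The fit is restarted from several seeded random label
assignments and the restart with the lowest final objective is returned.

The sparsity exponent ``p`` must exceed 1: at ``p = 1`` the weight update
degenerates to winner-take-all on a single kernel.  Values in {1.5, 2, 2.5}
are the useful range; smaller p concentrates the weights, larger p flattens
them toward uniform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import AssignmentError, ParameterError
from .kernels import KernelBank

__all__ = [
    "MVKKMConfig",
    "MVKKMResult",
    "view_distortion",
    "update_weights",
    "kernel_kmeans_step",
    "mvkkm_fit",
    "aggregate_view_weights",
]


@dataclass
class MVKKMConfig:
    """Knobs of one MVKKM fit.

    ``k`` is the cluster count, ``p > 1`` the sparsity exponent of the
    composite kernel, ``n_restarts`` the number of seeded random
    initializations, and ``tol`` the relative objective-change threshold
    (combined with label stability) that defines convergence.
    """

    k: int = 2
    p: float = 1.5
    max_iter: int = 100
    tol: float = 1e-8
    n_restarts: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.p <= 1:
            raise ParameterError("p must be > 1 (p = 1 degenerates to one view)")
        if self.n_restarts < 1 or self.max_iter < 1:
            raise ParameterError("n_restarts and max_iter must be >= 1")


@dataclass
class MVKKMResult:
    labels: np.ndarray
    weights: np.ndarray
    view_weights: dict[str, float]
    objective_trace: list[float]
    k: int
    p: float
    restart_objectives: list[float]
    converged: bool
    n_iter: int = 0
    seed: int = 0

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.tolist(),
            "weights": self.weights.tolist(),
            "view_weights": self.view_weights,
            "objective_trace": self.objective_trace,
            "k": self.k,
            "p": self.p,
            "restart_objectives": self.restart_objectives,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _check_labels(labels: np.ndarray, n: int, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (n,):
        raise AssignmentError(f"labels must have shape ({n},)")
    if labels.min() < 0 or labels.max() >= k:
        raise AssignmentError("labels out of range for k clusters")
    return labels


def view_distortion(K: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster scatter of one kernel's feature space.

    Every cluster referenced by ``labels`` must be nonempty (clusters are the
    distinct values present; an explicitly empty cluster cannot be expressed
    here and is repaired at fit level instead).
    """
    K = np.asarray(K, dtype=float)
    labels = np.asarray(labels, dtype=int)
    total = float(np.trace(K))
    within = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        within += K[np.ix_(idx, idx)].sum() / idx.size
    return max(total - within, 0.0)


def _bank_distortions(stacked: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """view_distortion for every kernel of a stacked (m, n, n) bank at once."""
    m = stacked.shape[0]
    total = np.trace(stacked, axis1=1, axis2=2)
    within = np.zeros(m)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sub = stacked[:, idx][:, :, idx]
        within += sub.sum(axis=(1, 2)) / idx.size
    return np.clip(total - within, 0.0, None)


def update_weights(distortions: Sequence[float], p: float) -> np.ndarray:
    """Simplex weights minimizing ``sum_v w_v^p D_v`` for fixed distortions.

    Closed form ``w_v = D_v^(-1/(p-1)) / sum_u D_u^(-1/(p-1))``.  Kernels with
    zero distortion take all the weight (split uniformly among them), which is
    the limit of the closed form.
    """
    if p <= 1:
        raise ParameterError("p must be > 1")
    D = np.asarray(distortions, dtype=float)
    if (D < 0).any():
        raise ParameterError("distortions must be nonnegative")
    zero = D <= 0.0
    if zero.any():
        w = np.zeros_like(D)
        w[zero] = 1.0 / zero.sum()
        return w
    w = D ** (-1.0 / (p - 1.0))
    return w / w.sum()


def kernel_kmeans_step(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """One assignment pass of kernel k-means on a (composite) Gram matrix.

    Each sample moves to the cluster whose frozen centroid (computed from the
    input labels) is nearest in feature space; assignment ties break toward
    the lowest cluster index.  The composite distortion cannot increase.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    labels = _check_labels(labels, n, k)
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise AssignmentError("every current cluster must be nonempty")
    Z = np.zeros((n, k))
    Z[np.arange(n), labels] = 1.0
    S = K @ Z  # (n, k): sum over cluster members of K_ij
    quad = np.einsum("nc,nd->cd", Z, S)[np.arange(k), np.arange(k)]  # Z_c' K Z_c
    dist = (
        np.diag(K)[:, None]
        - 2.0 * S / counts[None, :]
        + (quad / counts**2)[None, :]
    )
    return np.argmin(dist, axis=1)


def _repair_empty(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Deterministically refill empty clusters.

    The sample farthest from its own centroid in the composite feature space
    is moved into the empty cluster (never emptying another cluster in turn).
    """
    labels = labels.copy()
    n = K.shape[0]
    for c in range(k):
        while not (labels == c).any():
            # squared feature-space distance of each sample to its centroid
            cen_dist = np.empty(n)
            for cc in np.unique(labels):
                idx = np.flatnonzero(labels == cc)
                sub = K[np.ix_(idx, idx)]
                # ||phi_i - mu_c||^2 = K_ii - 2 mean_j K_ij + mean_jl K_jl
                cen = (
                    np.diag(sub)
                    - 2.0 * sub.mean(axis=1)
                    + sub.sum() / idx.size**2
                )
                cen_dist[idx] = cen
            counts = np.bincount(labels, minlength=k)
            movable = counts[labels] > 1
            cen_dist[~movable] = -np.inf
            labels[int(np.argmax(cen_dist))] = c
    return labels


def _composite_values(stacked: np.ndarray, w: np.ndarray, p: float) -> np.ndarray:
    return np.tensordot(w**p, stacked, axes=1)


def mvkkm_fit(
    bank: KernelBank,
    config: MVKKMConfig,
    *,
    init_labels: np.ndarray | None = None,
) -> MVKKMResult:
    """Fit MVKKM with restarts and return the lowest-objective solution.

    Each restart starts from uniform kernel weights and a seeded uniform
    random label assignment (or ``init_labels`` for the first restart, which
    is how deterministic starts for oracle comparisons are expressed), then
    alternates assignment sweeps to label convergence with the closed-form
    weight update until the relative objective change drops below
    ``config.tol`` with stable labels.
    """
    n = bank.n_samples
    k, p = config.k, config.p
    if k > n:
        raise ParameterError(f"k={k} exceeds n={n}")
    stacked = bank.stacked()
    m = stacked.shape[0]
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)

    best: MVKKMResult | None = None
    restart_objectives: list[float] = []
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if r == 0 and init_labels is not None:
            labels = _check_labels(init_labels, n, k)
        else:
            labels = rng.integers(0, k, size=n)
        w = np.full(m, 1.0 / m)
        Kc = _composite_values(stacked, w, p)
        labels = _repair_empty(Kc, labels, k)

        trace: list[float] = []
        converged = False
        prev_obj = np.inf
        prev_labels = labels.copy()
        it = 0
        for it in range(1, config.max_iter + 1):
            Kc = _composite_values(stacked, w, p)
            # assignment sweeps to label convergence on the current composite
            for _ in range(100):
                new = kernel_kmeans_step(Kc, labels, k)
                if (np.bincount(new, minlength=k) == 0).any():
                    new = _repair_empty(Kc, new, k)
                if np.array_equal(new, labels):
                    break
                labels = new
            D = _bank_distortions(stacked, labels)
            w = update_weights(D, p)
            obj = float(np.sum(w**p * D))
            trace.append(obj)
            labels_stable = np.array_equal(labels, prev_labels)
            rel = abs(prev_obj - obj) / max(abs(prev_obj), 1e-300)
            if labels_stable and rel < config.tol:
                converged = True
                break
            prev_obj = obj
            prev_labels = labels.copy()

        restart_objectives.append(trace[-1])
        if best is None or trace[-1] < best.objective:
            best = MVKKMResult(
                labels=labels.copy(),
                weights=w.copy(),
                view_weights={},
                objective_trace=trace,
                k=k,
                p=p,
                restart_objectives=[],
                converged=converged,
                n_iter=it,
                seed=config.seed,
            )

    assert best is not None
    best.restart_objectives = restart_objectives
    best.view_weights = aggregate_view_weights(best, bank)
    return best


def aggregate_view_weights(result: MVKKMResult, bank: KernelBank) -> dict[str, float]:
    """Sum the learned per-kernel weights within each view (sums total 1)."""
    if len(result.weights) != len(bank):
        raise ParameterError("result weights do not match bank size")
    sums: dict[str, float] = {v: 0.0 for v in bank.views}
    for w, kern in zip(result.weights, bank):
        sums[kern.view] += float(w)
    return sums
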