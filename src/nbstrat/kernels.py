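"""RBF kernel banks and the weighted composite kernel.

Each expression view is mapped to a bank of Gram matrices
``K(x, y) = exp(-gamma * ||x - y||^2)`` over a grid of bandwidths, and the
banks of all views are combined into the composite kernel

    K~ = sum_v  w_v^p  K^(v)

with nonnegative weights on the simplex and a sparsity exponent ``p >= 1``.
The default bandwidth grid is {2^-14, ..., 2^-19}, matched to log2-scale
expression matrices with thousands of genes, where squared sample-to-sample
distances run in the thousands to hundreds of thousands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel

from .exceptions import ParameterError, ValidationError
from .io_harmonize import MultiViewDataset

__all__ = [
    "DEFAULT_GAMMAS",
    "GramMatrix",
    "KernelBank",
    "CompositeKernel",
    "rbf_gram",
    "build_kernel_bank",
    "composite_kernel",
    "kernel_distance",
    "save_bank",
    "load_bank",
]

#: Bandwidth grid used throughout: six gammas spanning 2^-14 .. 2^-19.
DEFAULT_GAMMAS: tuple[float, ...] = tuple(2.0**-e for e in range(14, 20))


@dataclass
class GramMatrix:
    """A single RBF Gram matrix tagged with its view and bandwidth."""

    values: np.ndarray
    view: str
    gamma: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("Gram matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("Gram matrix must be symmetric")
        if self.gamma <= 0:
            raise ParameterError("gamma must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class KernelBank:
    """Ordered Gram matrices over one shared sample set (view-major order)."""

    kernels: list[GramMatrix]

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValidationError("empty kernel bank")
        n = self.kernels[0].n
        if any(k.n != n for k in self.kernels):
            raise ValidationError("all kernels in a bank must share one dimension")

    @property
    def n_samples(self) -> int:
        return self.kernels[0].n

    @property
    def views(self) -> list[str]:
        """View labels in first-appearance (bank) order."""
        return list(dict.fromkeys(k.view for k in self.kernels))

    def __len__(self) -> int:
        return len(self.kernels)

    def __iter__(self):
        return iter(self.kernels)

    def stacked(self) -> np.ndarray:
        """All Gram matrices as one (n_kernels, n, n) array."""
        return np.stack([k.values for k in self.kernels])


@dataclass
class CompositeKernel:
    """The weighted combination ``sum_v w_v^p K^(v)`` with its recipe."""

    values: np.ndarray
    weights: np.ndarray
    p: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def rbf_gram(X: np.ndarray, gamma: float, *, view: str = "") -> GramMatrix:
    """RBF Gram matrix of the rows of ``X``; the diagonal is exactly 1."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in feature matrix")
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    K = rbf_kernel(X, gamma=gamma)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return GramMatrix(values=K, view=view, gamma=float(gamma))


def build_kernel_bank(
    data: MultiViewDataset, gammas: Sequence[float] = DEFAULT_GAMMAS
) -> KernelBank:
    """One RBF Gram matrix per (view, gamma), in view-major, gamma-minor order."""
    if len(gammas) == 0:
        raise ParameterError("need at least one gamma")
    kernels: list[GramMatrix] = []
    for view in data.views:
        if view.n_genes == 0:
            raise ValidationError(f"view {view.name!r} has no features")
        for gamma in gammas:
            kernels.append(rbf_gram(view.values, gamma, view=view.name))
    return KernelBank(kernels)


def composite_kernel(
    bank: KernelBank, weights: Sequence[float], p: float
) -> CompositeKernel:
    """Combine a bank into ``K~ = sum w^p K`` after validating the simplex."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(bank),):
        raise ParameterError(f"need {len(bank)} weights, got {w.shape}")
    if (w < 0).any():
        raise ParameterError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ParameterError(f"weights must sum to 1, got {w.sum():.8f}")
    if p < 1:
        raise ParameterError("p must be >= 1")
    values = np.tensordot(w**p, bank.stacked(), axes=1)
    return CompositeKernel(values=values, weights=w, p=float(p))


def kernel_distance(K: CompositeKernel | GramMatrix | np.ndarray) -> np.ndarray:
    """Feature-space distances ``d(i,j) = sqrt(K_ii + K_jj - 2 K_ij)``.

    Negative radicands from floating point are clipped at zero; the result has
    an exactly zero diagonal and is symmetric.
    """
    V = K if isinstance(K, np.ndarray) else K.values
    diag = np.diag(V)
    sq = diag[:, None] + diag[None, :] - 2.0 * V
    d = np.sqrt(np.clip(sq, 0.0, None))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def save_bank(bank: KernelBank, directory: str | Path) -> None:
    """Serialize a bank to a directory of TSV matrices plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, k in enumerate(bank):
        fname = f"kernel_{i:03d}.tsv"
        np.savetxt(directory / fname, k.values, delimiter="\t", fmt="%.17g")
        manifest.append({"file": fname, "view": k.view, "gamma": k.gamma})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bank(directory: str | Path) -> KernelBank:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    kernels = [
        GramMatrix(
            values=np.loadtxt(directory / entry["file"], delimiter="\t", ndmin=2),
            view=entry["view"],
            gamma=entry["gamma"],
        )
        for entry in manifest
    ]
    return KernelBank(kernels)
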