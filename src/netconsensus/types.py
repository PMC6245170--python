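"""Shared data containers.

Partitions are represented throughout the package as 1-D integer numpy
arrays: entry ``i`` is the community label of node ``i`` (0-based node
ids).  Labels are arbitrary; every derived quantity (modularity, NMI)
is invariant under relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedGraph",
    "SubjectEnsemble",
    "as_partition",
]

_SYMMETRY_TOL = 1e-12


def as_partition(labels, n_nodes: int | None = None) -> np.ndarray:
    """Coerce ``labels`` to a validated partition array."""
    p = np.asarray(labels)
    if p.ndim != 1:
        raise ValueError(f"partition must be 1-D, got shape {p.shape}")
    if p.size == 0:
        raise ValueError("partition is empty")
    if not np.issubdtype(p.dtype, np.integer):
        if not np.all(p == np.floor(p)):
            raise ValueError("community labels must be integers")
        p = p.astype(np.int64)
    if n_nodes is not None and p.size != n_nodes:
        raise ValueError(f"partition covers {p.size} nodes, expected {n_nodes}")
    return p


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric weighted ROI x ROI matrix with zero diagonal.

    ``scale`` is ``"correlation"`` (entries in [-1, 1]) or ``"fisher_z"``
    (atanh of correlations, unbounded).
    """

    weights: np.ndarray
    scale: str = "correlation"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if np.isnan(w).any():
            raise ValueError("weights contain NaN")
        if np.abs(w - w.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("weights are not symmetric within 1e-12")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        if self.scale not in ("correlation", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "correlation" and np.abs(w).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("correlation-scale entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdedGraph:
    """Weighted undirected graph retaining the top fraction ``density``
    of the ``n_nodes * (n_nodes - 1) / 2`` possible edges.

    ``adjacency`` is dense, symmetric, non-negative, zero-diagonal.
    """

    adjacency: np.ndarray
    density: float
    n_nodes: int = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if np.abs(a - a.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("adjacency is not symmetric")
        if (a < 0).any():
            raise ValueError("adjacency has negative weights")
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        a.flags.writeable = False
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "n_nodes", a.shape[0])
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def total_weight(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(self.adjacency.sum() / 2.0)

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(a), int(b), float(self.adjacency[a, b])) for a, b in zip(i, j)]


@dataclass(frozen=True)
class SubjectEnsemble:
    """Ordered collection of per-subject connectivity matrices on a
    shared node set."""

    matrices: tuple
    subject_ids: tuple = None

    def __post_init__(self):
        mats = tuple(self.matrices)
        if not mats:
            raise ValueError("ensemble is empty")
        for m in mats:
            if not isinstance(m, ConnectivityMatrix):
                raise TypeError("matrices must be ConnectivityMatrix instances")
        n = mats[0].n_nodes
        for k, m in enumerate(mats):
            if m.n_nodes != n:
                raise ValueError(
                    f"subject {k} has {m.n_nodes} nodes, expected {n}"
                )
        object.__setattr__(self, "matrices", mats)
        ids = self.subject_ids
        if ids is None:
            ids = tuple(f"sub-{k:02d}" for k in range(len(mats)))
        else:
            ids = tuple(ids)
            if len(ids) != len(mats):
                raise ValueError("subject_ids length mismatch")
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_nodes(self) -> int:
        return self.matrices[0].n_nodes

    def mean_matrix(self) -> ConnectivityMatrix:
        """Element-wise mean across subjects, on the matrices' own scale."""
        w = np.mean([m.weights for m in self.matrices], axis=0)
        scale = self.matrices[0].scale
        if scale == "correlation" and np.abs(w).max() > 1:
            w = np.clip(w, -1.0, 1.0)
        return ConnectivityMatrix(w, scale=scale)
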