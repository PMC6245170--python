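"""Partition similarity: confusion matrix and Normalized Mutual Information.

NMI is computed from the community-overlap confusion matrix with natural
logarithms and the arithmetic-mean normalization 2 I(A;B) / (H(A) + H(B))
(Danon/Fortunato convention); the geometric-mean (Strehl-Ghosh)
normalization I / sqrt(H(A) H(B)) is available as an option.  The value
is 1 iff the partitions are identical up to relabeling and 0 when they
are independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .types import as_partition

__all__ = ["ConfusionMatrix", "confusion", "nmi", "pairwise_nmi"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Shared-node counts between the communities of two partitions.

    ``counts[a, b]`` is the number of nodes in community ``row_labels[a]``
    of the first partition and ``col_labels[b]`` of the second.
    """

    counts: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion(p1, p2) -> ConfusionMatrix:
    """Community-overlap table of two partitions of the same node set."""
    a = as_partition(p1)
    b = as_partition(p2)
    if a.size != b.size:
        raise ValueError(
            f"partitions cover different node sets: {a.size} vs {b.size} nodes"
        )
    row_labels, ai = np.unique(a, return_inverse=True)
    col_labels, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((row_labels.size, col_labels.size), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ConfusionMatrix(counts, row_labels, col_labels)


def _entropy(sizes: np.ndarray, n: int) -> float:
    p = sizes[sizes > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(p1, p2, normalization: str = "arithmetic") -> float:
    """Normalized Mutual Information between two partitions, in [0, 1].

    Degenerate single-community cases follow the continuity convention:
    two identical trivial partitions give 1.0; if exactly one partition
    is trivial (zero entropy) the mutual information is 0 and so is the
    NMI.
    """
    if normalization not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown normalization {normalization!r}")
    cm = confusion(p1, p2)
    n = cm.n
    nij = cm.counts
    a = nij.sum(axis=1)
    b = nij.sum(axis=0)
    h1 = _entropy(a, n)
    h2 = _entropy(b, n)
    if h1 == 0.0 and h2 == 0.0:
        return 1.0  # both trivial, hence identical on the same node set
    if h1 == 0.0 or h2 == 0.0:
        return 0.0
    nz = nij > 0
    pij = nij[nz] / n
    outer = np.outer(a, b)[nz] / (n * n)
    mi = float((pij * np.log(pij / outer)).sum())
    if normalization == "arithmetic":
        val = 2.0 * mi / (h1 + h2)
    else:
        val = mi / np.sqrt(h1 * h2)
    return float(min(max(val, 0.0), 1.0))


def pairwise_nmi(partitions, normalization: str = "arithmetic") -> np.ndarray:
    """Symmetric unit-diagonal matrix of NMI values for every pair."""
    parts = [as_partition(p) for p in partitions]
    if len(parts) < 2:
        raise ValueError("need at least 2 partitions")
    k = len(parts)
    out = np.eye(k)
    for i, j in combinations(range(k), 2):
        out[i, j] = out[j, i] = nmi(parts[i], parts[j], normalization)
    return out
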