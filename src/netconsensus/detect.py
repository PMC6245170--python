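"""Modularity, seeded Louvain, and the three group-level detection schemes.

Three ways to get one community structure for a group of subjects:

* **VTS** (virtual typical subject): average the subjects' unthresholded
  connectivity matrices, threshold the mean, run Louvain on it.
* **IS** (individual structure): run Louvain per subject, compute all
  pairwise NMI values between subjects' partitions, and return the
  partition of the subject with the highest mean NMI to the others.
* **GA** (group analysis): a group-level Louvain that evaluates every
  candidate local move on each subject's own thresholded graph and
  applies the move maximizing the *trimmed mean* modularity change,
  excluding subjects whose change falls outside a percentile band
  (default 25th-75th) for that candidate move.

All Louvain variants share one engine: the single-subject algorithm is
the group algorithm with one graph and no trimming, so "N identical
subjects" reduces exactly to plain Louvain.  Randomness enters only
through the seeded node-visit order, making every run reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .construct import threshold_by_density
from .similarity import pairwise_nmi
from .types import ConnectivityMatrix, SubjectEnsemble, ThresholdedGraph, as_partition

__all__ = [
    "modularity",
    "louvain",
    "best_of_n",
    "detect_vts",
    "detect_is",
    "detect_ga",
    "recalc_modularity",
]

_GAIN_TOL = 1e-12


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def modularity(graph: ThresholdedGraph, partition) -> float:
    """Weighted Newman-Girvan modularity Q of a partition.

    Q = sum_c [ W_c / W  -  (S_c / 2W)^2 ] with W the total edge weight,
    W_c the intra-community weight and S_c the summed node strength of
    community c.  Q = 0 for the single-community partition; Q <= 1.
    """
    p = as_partition(partition, n_nodes=graph.n_nodes)
    adj = graph.adjacency
    two_w = adj.sum()
    if two_w <= 0:
        raise ValueError("graph has no edges; modularity undefined")
    _, idx = np.unique(p, return_inverse=True)
    n_comm = idx.max() + 1
    onehot = np.zeros((graph.n_nodes, n_comm))
    onehot[np.arange(graph.n_nodes), idx] = 1.0
    intra = np.einsum("ic,ij,jc->c", onehot, adj, onehot)  # 2 * W_c
    strength = adj.sum(axis=1) @ onehot  # S_c
    return float((intra / two_w - (strength / two_w) ** 2).sum())


# ---------------------------------------------------------------------------
# Louvain engine (single-subject and group variants share it)
# ---------------------------------------------------------------------------


def _trimmed_mean(delta: np.ndarray, band: tuple[float, float] | None) -> np.ndarray:
    """Mean over subjects (axis 0) after excluding, per column, values
    outside the percentile band.  Falls back to the full mean if a band
    would exclude everything."""
    if band is None or delta.shape[0] == 1:
        return delta.mean(axis=0)
    lo, hi = np.percentile(delta, band, axis=0)
    mask = (delta >= lo) & (delta <= hi)
    counts = mask.sum(axis=0)
    empty = counts == 0
    if empty.any():  # degenerate band (e.g. (60, 40)); keep everything
        warnings.warn(
            "percentile band excluded all subjects for some moves; "
            "falling back to the untrimmed mean",
            stacklevel=2,
        )
        mask = mask | empty[None, :]
        counts = mask.sum(axis=0)
    return (delta * mask).sum(axis=0) / counts


def _local_phase(
    adj: np.ndarray,
    comm: np.ndarray,
    rng: np.random.Generator,
    band: tuple[float, float] | None,
) -> bool:
    """One complete local-move phase, in place on ``comm``.

    ``adj`` is (S, n, n); diagonals hold 2x the collapsed self-loop
    weight so that row sums are node strengths.  Returns True if any
    node moved.
    """
    n_sub, n, _ = adj.shape
    two_m = adj.sum(axis=(1, 2))  # per subject, == 2m_s
    if (two_m <= 0).any():
        empty = np.nonzero(two_m <= 0)[0].tolist()
        raise ValueError(f"subject graph(s) {empty} have no edges")
    strength = adj.sum(axis=2)  # (S, n)
    n_comm = comm.max() + 1
    sigma = np.zeros((n_sub, n_comm))
    for s in range(n_sub):
        sigma[s] = np.bincount(comm, weights=strength[s], minlength=n_comm)

    moved_any = False
    improving = True
    while improving:
        improving = False
        for i in rng.permutation(n):
            a = comm[i]
            rows = adj[:, i, :].copy()
            rows[:, i] = 0.0  # self weight never counts as a link to a community
            k_ic = np.empty((n_sub, n_comm))
            for s in range(n_sub):
                k_ic[s] = np.bincount(comm, weights=rows[s], minlength=n_comm)
            ki = strength[:, i]
            sigma[:, a] -= ki
            # gain of inserting isolated node i into community c:
            # k_{i,c}/m - k_i * Sigma_tot(c) / (2 m^2), per subject
            m = two_m[:, None] / 2.0
            gains = k_ic / m - ki[:, None] * sigma / (2.0 * m**2)
            # candidates: communities i touches in any subject, plus home
            cand = np.nonzero(k_ic.sum(axis=0) > 0)[0]
            if a not in cand:
                cand = np.append(cand, a)
            cand.sort()
            delta = gains[:, cand] - gains[:, [a]]
            score = _trimmed_mean(delta, band)
            best = int(np.argmax(score))
            target = int(cand[best])
            if score[best] > _GAIN_TOL and target != a:
                comm[i] = target
                sigma[:, target] += ki
                moved_any = True
                improving = True
            else:
                sigma[:, a] += ki
    return moved_any


def _group_louvain(
    adj_stack: np.ndarray,
    rng: np.random.Generator,
    band: tuple[float, float] | None,
) -> np.ndarray:
    """Full two-phase Louvain on a stack of subject graphs; returns the
    node -> community assignment on the original node set."""
    adj = adj_stack.astype(float, copy=True)
    if adj.sum() <= 0:
        raise ValueError("empty graph: no edges to optimize over")
    n0 = adj.shape[1]
    labels = np.arange(n0)
    while True:
        comm = np.arange(adj.shape[1])
        moved = _local_phase(adj, comm, rng, band)
        _, comm = np.unique(comm, return_inverse=True)
        labels = comm[labels]
        if not moved or comm.max() + 1 == adj.shape[1]:
            break
        n_comm = comm.max() + 1
        onehot = np.zeros((adj.shape[1], n_comm))
        onehot[np.arange(adj.shape[1]), comm] = 1.0
        # collapse communities in every subject's graph in parallel;
        # diagonals accumulate 2x intra weight, preserving strengths
        adj = np.einsum("ic,sij,jd->scd", onehot, adj, onehot)
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def louvain(graph: ThresholdedGraph, seed: int) -> tuple[np.ndarray, float]:
    """One seeded Louvain run; returns (partition, its modularity Q).

    Run-to-run variation comes only from the seeded shuffling of the
    node visit order, so a fixed graph and seed always reproduce the
    same partition.
    """
    rng = np.random.default_rng(_seedseq(seed))
    labels = _group_louvain(graph.adjacency[None, :, :], rng, band=None)
    return labels, modularity(graph, labels)


def best_of_n(
    graph: ThresholdedGraph, n_runs: int = 100, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Run Louvain ``n_runs`` times and keep the highest-Q partition.

    Each run uses an independent child seed of ``seed``.  Among equal
    highest Q values the earliest run wins, so the result is
    deterministic.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    best_labels, best_q = None, -np.inf
    for child in _seedseq(seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        labels = _group_louvain(graph.adjacency[None, :, :], rng, band=None)
        q = modularity(graph, labels)
        if q > best_q + _GAIN_TOL:
            best_labels, best_q = labels, q
    return best_labels, best_q


# ---------------------------------------------------------------------------
# Group-level detection schemes
# ---------------------------------------------------------------------------


def _thresholded_graphs(ensemble: SubjectEnsemble, density: float) -> list[ThresholdedGraph]:
    return [threshold_by_density(m, density) for m in ensemble.matrices]


def detect_vts(
    ensemble: SubjectEnsemble,
    density: float,
    n_runs: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Virtual-typical-subject: Louvain (best of ``n_runs``) on the
    subject-averaged connectivity matrix, thresholded at ``density``.
    The average is taken on the unthresholded matrices."""
    mean = ensemble.mean_matrix()
    graph = threshold_by_density(mean, density)
    labels, _ = best_of_n(graph, n_runs=n_runs, seed=seed)
    return labels


@dataclass(frozen=True)
class ISResult:
    partition: np.ndarray
    representative: str
    representative_index: int
    mean_nmi: np.ndarray  # per-subject mean pairwise NMI (self excluded)


def detect_is(
    ensemble: SubjectEnsemble,
    density: float,
    n_runs: int = 100,
    seed: int = 0,
) -> ISResult:
    """Individual-structure: detect each subject's partition, then pick
    the subject whose partition has the highest mean pairwise NMI with
    all other subjects (self-pair excluded; ties go to the lowest
    subject index)."""
    if ensemble.n_subjects < 2:
        raise ValueError("IS approach needs at least 2 subjects")
    seeds = _seedseq(seed).spawn(ensemble.n_subjects)
    parts = [
        best_of_n(g, n_runs=n_runs, seed=s)[0]
        for g, s in zip(_thresholded_graphs(ensemble, density), seeds)
    ]
    nmi_mat = pairwise_nmi(parts)
    np.fill_diagonal(nmi_mat, 0.0)
    means = nmi_mat.sum(axis=1) / (ensemble.n_subjects - 1)
    rep = int(np.argmax(means))  # argmax returns the first (lowest) index on ties
    return ISResult(parts[rep], ensemble.subject_ids[rep], rep, means)


def detect_ga(
    ensemble: SubjectEnsemble,
    density: float,
    outlier_band: tuple[float, float] = (25.0, 75.0),
    n_runs: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Group-analysis Louvain over each subject's own thresholded graph.

    At every candidate local move the modularity change is computed on
    each subject's graph; subjects outside ``outlier_band`` percentiles
    of those changes are excluded and the move maximizing the trimmed
    mean change is applied.  Phase-2 aggregation collapses communities
    in all subjects' graphs in parallel.  Of ``n_runs`` seeded runs the
    partition with the highest subject-mean recalculated Q is returned.
    """
    if ensemble.n_subjects < 2:
        raise ValueError("GA approach needs at least 2 subjects")
    graphs = _thresholded_graphs(ensemble, density)
    stack = np.stack([g.adjacency for g in graphs])
    best_labels, best_score = None, -np.inf
    for child in _seedseq(seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        labels = _group_louvain(stack, rng, band=outlier_band)
        score = float(np.mean([modularity(g, labels) for g in graphs]))
        if score > best_score + _GAIN_TOL:
            best_labels, best_score = labels, score
    return best_labels


def recalc_modularity(partition, ensemble: SubjectEnsemble, density: float) -> np.ndarray:
    """Per-subject Q of a fixed (group-based) partition, evaluated on
    each subject's own graph thresholded at ``density``.  These values
    are what the modularity permutation tests consume."""
    p = as_partition(partition, n_nodes=ensemble.n_nodes)
    return np.array(
        [modularity(g, p) for g in _thresholded_graphs(ensemble, density)]
    )
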