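"""Synthetic multi-subject ensembles with a planted community structure.

The generator emulates a resting-state study: ``n_subjects`` weighted
undirected networks on a common node set that share a planted partition,
each corrupted by subject-specific noise.  Two noise knobs are separated
on purpose: ``weight_sd`` perturbs edge weights (additive Gaussian),
``rewire_prob`` perturbs topology (an edge's block identity is swapped,
so a within-community pair draws its weight from the between-community
level and vice versa).

Defaults mirror a typical 90-ROI (AAL-90 sized), 20-subject study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ConnectivityMatrix, SubjectEnsemble, as_partition

__all__ = [
    "PlantedEnsembleSpec",
    "GroundTruth",
    "generate_ensemble",
    "generate_block_timeseries",
]


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Parameters of a planted-partition ensemble.

    ``w_in`` / ``w_out`` are the mean within- and between-community edge
    weights on the correlation scale (dimensionless, 0-1); ``weight_sd``
    is the per-subject additive noise scale; ``rewire_prob`` is the
    per-subject probability that a node pair swaps its block identity.
    """

    n_nodes: int = 90
    community_sizes: tuple = (10,) * 9
    n_subjects: int = 20
    w_in: float = 0.6
    w_out: float = 0.1
    weight_sd: float = 0.05
    rewire_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.community_sizes)
        object.__setattr__(self, "community_sizes", sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("community sizes must be positive")
        if sum(sizes) != self.n_nodes:
            raise ValueError(
                f"community_sizes sum to {sum(sizes)}, expected n_nodes={self.n_nodes}"
            )
        if not (self.w_in > self.w_out >= 0):
            raise ValueError("require w_in > w_out >= 0")
        if not (0 <= self.rewire_prob <= 1):
            raise ValueError("rewire_prob must be in [0, 1]")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    @property
    def n_communities(self) -> int:
        return len(self.community_sizes)

    def planted_partition(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_communities), self.community_sizes)


@dataclass(frozen=True)
class GroundTruth:
    """The planted partition, kept only so that simulations are testable;
    the comparison framework itself never consumes it."""

    partition: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "partition", as_partition(self.partition))


def generate_ensemble(spec: PlantedEnsembleSpec) -> tuple[SubjectEnsemble, GroundTruth]:
    """Draw ``spec.n_subjects`` symmetric zero-diagonal matrices sharing
    the planted block structure.

    Before noise, a within-community pair has expected weight ``w_in``
    and a between-community pair ``w_out``.  Per subject, each node pair
    independently swaps block identity with probability ``rewire_prob``,
    then Gaussian noise of scale ``weight_sd`` is added, the matrix is
    symmetrized, clipped to [-1, 1], and the diagonal zeroed.  Identical
    spec and seed give a bit-identical ensemble.
    """
    labels = spec.planted_partition()
    same_block = labels[:, None] == labels[None, :]
    base = np.where(same_block, spec.w_in, spec.w_out)
    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    mats = []
    for _ in range(spec.n_subjects):
        w = base.copy()
        if spec.rewire_prob > 0:
            flip = rng.random(iu[0].size) < spec.rewire_prob
            swapped = np.where(same_block[iu], spec.w_out, spec.w_in)
            upper = np.where(flip, swapped, base[iu])
        else:
            upper = base[iu].copy()
        if spec.weight_sd > 0:
            upper = upper + rng.normal(0.0, spec.weight_sd, size=upper.shape)
        w = np.zeros((n, n))
        w[iu] = upper
        w = w + w.T
        np.clip(w, -1.0, 1.0, out=w)
        mats.append(ConnectivityMatrix(w, scale="correlation"))
    return SubjectEnsemble(tuple(mats)), GroundTruth(labels)


def generate_block_timeseries(
    partition,
    n_timepoints: int,
    rho_in: float,
    rho_out: float,
    seed: int,
) -> np.ndarray:
    """ROI x time Gaussian series with exchangeable block correlations.

    Same-community ROI pairs have population correlation ``rho_in``,
    different-community pairs ``rho_out``; all variances are 1.  The
    sample correlation of a same-community pair converges to ``rho_in``
    as ``n_timepoints`` grows.

    Raises ``ValueError`` if the implied covariance matrix is not
    positive semi-definite for the given ``rho_in``/``rho_out``.
    """
    labels = as_partition(partition)
    if not (0 <= rho_out <= rho_in < 1):
        raise ValueError("require 0 <= rho_out <= rho_in < 1")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, rho_in, rho_out).astype(float)
    np.fill_diagonal(cov, 1.0)
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"implied covariance is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}) for rho_in={rho_in}, rho_out={rho_out}"
        )
    # tiny ridge so Cholesky succeeds on the PSD boundary
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(labels.size))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return chol @ rng.standard_normal((labels.size, n_timepoints))
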