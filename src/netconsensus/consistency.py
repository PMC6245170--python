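"""Run-to-run consistency of the group detection algorithms.

Louvain is a heuristic, so a best-of-100 protocol is only worthwhile if
single runs actually vary.  This module re-runs a group approach (VTS
or GA) ``n_runs`` times with distinct seeds — no best-of selection —
against a fixed set of individual partitions, and summarizes (i) the
per-run subject-mean NMI with the individual structures (mean and SD
across runs) and (ii) the all-pairs NMI among the ``n_runs`` detected
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construct import threshold_by_density
from .detect import _group_louvain, _seedseq, best_of_n
from .similarity import nmi, pairwise_nmi
from .types import SubjectEnsemble

__all__ = ["IterationReport", "iteration_consistency"]


@dataclass(frozen=True)
class IterationReport:
    per_iteration_mean_nmi: np.ndarray  # length n_runs
    mean: float
    sd: float
    pairwise_mean: float
    pairwise_sd: float
    approach: str
    density: float


def iteration_consistency(
    ensemble: SubjectEnsemble,
    approach: str,
    density: float,
    n_runs: int = 100,
    seed: int = 0,
    indiv_n_runs: int = 100,
) -> IterationReport:
    """Variability of ``approach`` in {"vts", "ga"} over ``n_runs``
    single executions at one density level.

    Individual partitions are detected once (best of ``indiv_n_runs``
    per subject) and held fixed, so the report isolates the group
    method's own run-to-run variability.
    """
    approach = approach.lower()
    if approach not in ("vts", "ga"):
        raise ValueError(
            f"consistency analysis covers 'vts' and 'ga', got {approach!r}"
        )
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")

    root = _seedseq(seed)
    s_indiv, s_runs = root.spawn(2)
    indiv = [
        best_of_n(threshold_by_density(m, density), n_runs=indiv_n_runs, seed=ss)[0]
        for m, ss in zip(ensemble.matrices, s_indiv.spawn(ensemble.n_subjects))
    ]

    if approach == "vts":
        stack = threshold_by_density(ensemble.mean_matrix(), density).adjacency[None]
        band = None
    else:
        stack = np.stack(
            [threshold_by_density(m, density).adjacency for m in ensemble.matrices]
        )
        band = (25.0, 75.0)

    parts = [
        _group_louvain(stack, np.random.default_rng(child), band)
        for child in s_runs.spawn(n_runs)
    ]
    per_run = np.array([np.mean([nmi(p, q) for q in indiv]) for p in parts])
    pw = pairwise_nmi(parts)
    vals = pw[np.triu_indices(n_runs, k=1)]
    return IterationReport(
        per_iteration_mean_nmi=per_run,
        mean=float(per_run.mean()),
        sd=float(per_run.std(ddof=0)),
        pairwise_mean=float(vals.mean()),
        pairwise_sd=float(vals.std(ddof=0)),
        approach=approach,
        density=density,
    )
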