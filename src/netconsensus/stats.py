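"""Permutation tests on per-subject scores and FDR control.

The comparison framework asks, per density level, whether one detection
scheme's group partition agrees better with the subjects' individual
partitions than another's.  Agreement per subject is an NMI (or a
recalculated modularity).  Two paired test statistics are offered:

* ``subject_count``: (# subjects with a > b) - (# subjects with b > a) —
  the method's headline statistic, robust to a single extreme subject;
* ``mean_difference``: mean(a) - mean(b) — the conventional alternative,
  more sensitive to outliers.

The null distribution flips each subject's (a, b) pair independently
with probability 1/2 (sign flip of the paired difference), the standard
exchangeability-preserving null for paired designs.  P-values use the
add-one estimator (b + 1) / (N + 1), two-sided.  Multiplicity across
density levels is controlled with Benjamini-Yekutieli FDR, valid under
arbitrary dependence between densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .detect import best_of_n, detect_ga, detect_is, detect_vts, recalc_modularity, threshold_by_density
from .similarity import nmi
from .types import SubjectEnsemble

__all__ = [
    "PermutationResult",
    "FDRReport",
    "subject_count_statistic",
    "permutation_test_counts",
    "permutation_test_means",
    "permutation_test_modularity",
    "fdr_correct",
    "compare_schemes",
]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_iterations: int
    statistic_kind: str
    seed: int


@dataclass(frozen=True)
class FDRReport:
    p_values: np.ndarray
    rejected: np.ndarray
    alpha: float


def _paired(scores_a, scores_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError(
            f"paired score vectors must be 1-D and equal length, "
            f"got {a.shape} and {b.shape}"
        )
    return a, b


def subject_count_statistic(scores_a, scores_b) -> int:
    """Number of subjects with a strictly greater score under A; ties
    count for neither side."""
    a, b = _paired(scores_a, scores_b)
    return int((a > b).sum())


def _count_stat(d: np.ndarray) -> np.ndarray:
    """Signed count statistic of paired differences along the last axis."""
    return (d > 0).sum(axis=-1) - (d < 0).sum(axis=-1)


def _signflip_test(
    scores_a, scores_b, n_iter: int, seed: int, kind: str
) -> PermutationResult:
    a, b = _paired(scores_a, scores_b)
    if a.size < 2:
        raise ValueError("need at least 2 subjects")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    d = a - b
    if kind == "subject_count":
        observed = float(_count_stat(d))
        stat = _count_stat
    elif kind == "mean_difference":
        observed = float(d.mean())
        stat = lambda x: x.mean(axis=-1)
    else:  # pragma: no cover
        raise ValueError(f"unknown statistic kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flips = rng.integers(0, 2, size=(n_iter, d.size)) * 2 - 1
    null = stat(d[None, :] * flips)
    p = (int((np.abs(null) >= abs(observed) - 1e-12).sum()) + 1) / (n_iter + 1)
    return PermutationResult(observed, float(p), n_iter, kind, seed)


def permutation_test_counts(
    scores_a, scores_b, n_iter: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Two-sided sign-flip permutation test on the subject-count statistic."""
    return _signflip_test(scores_a, scores_b, n_iter, seed, "subject_count")


def permutation_test_means(
    scores_a, scores_b, n_iter: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Two-sided sign-flip permutation test on the mean difference."""
    return _signflip_test(scores_a, scores_b, n_iter, seed, "mean_difference")


def permutation_test_modularity(
    q_a, q_b, n_iter: int = 10_000, seed: int = 0, kind: str = "subject_count"
) -> PermutationResult:
    """Permutation test on per-subject recalculated modularity vectors
    (same machinery as the NMI tests)."""
    return _signflip_test(q_a, q_b, n_iter, seed, kind)


def fdr_correct(p_values, alpha: float = 0.05) -> FDRReport:
    """Benjamini-Yekutieli step-up FDR control at level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    rejected, _, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return FDRReport(p, rejected, alpha)


# ---------------------------------------------------------------------------
# End-to-end scheme comparison driver
# ---------------------------------------------------------------------------

_DETECTORS = {
    "vts": lambda e, d, n_runs, seed: detect_vts(e, d, n_runs=n_runs, seed=seed),
    "is": lambda e, d, n_runs, seed: detect_is(e, d, n_runs=n_runs, seed=seed).partition,
    "ga": lambda e, d, n_runs, seed: detect_ga(e, d, n_runs=n_runs, seed=seed),
}


@dataclass(frozen=True)
class ComparisonReport:
    """Everything `compare_schemes` computes.

    ``nmi_table``: long-format per-subject agreement (subject, approach,
    density, nmi).  ``tests``: per approach pair, per density, the count
    test on NMI and on recalculated modularity.  ``fdr``: per pair and
    score type, the BY report across densities.
    """

    nmi_table: pd.DataFrame
    modularity_table: pd.DataFrame
    tests: pd.DataFrame
    fdr: dict
    group_partitions: dict = field(repr=False, default_factory=dict)


def compare_schemes(
    ensemble: SubjectEnsemble,
    approaches=("vts", "is", "ga"),
    densities=(0.1, 0.2, 0.3),
    n_runs: int = 100,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ComparisonReport:
    """Full comparison of detection schemes on one ensemble.

    For every density: detect each approach's group partition and every
    subject's individual partition, compute per-subject NMI between the
    group and individual structures and per-subject recalculated Q, run
    the pairwise count tests across approaches, then BY-correct across
    densities within each approach pair.  Deterministic given ``seed``.
    """
    approaches = [a.lower() for a in approaches]
    unknown = [a for a in approaches if a not in _DETECTORS]
    if unknown:
        raise ValueError(f"unknown approach(es) {unknown}; choose from {sorted(_DETECTORS)}")
    if len(approaches) < 2:
        raise ValueError("need at least 2 approaches to compare")

    root = np.random.SeedSequence(seed)
    s_detect, s_indiv, s_test = root.spawn(3)
    detect_seeds = {
        (a, d): ss
        for (a, d), ss in zip(
            [(a, d) for a in approaches for d in densities],
            s_detect.spawn(len(approaches) * len(densities)),
        )
    }
    indiv_seeds = dict(zip(densities, s_indiv.spawn(len(densities))))

    nmi_rows, q_rows = [], []
    group_partitions = {}
    for d in densities:
        # individual structures, shared across all approach comparisons
        subj_seeds = indiv_seeds[d].spawn(ensemble.n_subjects)
        indiv = [
            best_of_n(threshold_by_density(m, d), n_runs=n_runs, seed=ss)[0]
            for m, ss in zip(ensemble.matrices, subj_seeds)
        ]
        for a in approaches:
            part = _DETECTORS[a](ensemble, d, n_runs, detect_seeds[(a, d)])
            group_partitions[(a, d)] = part
            qs = recalc_modularity(part, ensemble, d)
            for s in range(ensemble.n_subjects):
                nmi_rows.append(
                    {
                        "subject": ensemble.subject_ids[s],
                        "approach": a,
                        "density": d,
                        "nmi": nmi(part, indiv[s]),
                    }
                )
                q_rows.append(
                    {
                        "subject": ensemble.subject_ids[s],
                        "approach": a,
                        "density": d,
                        "q": qs[s],
                    }
                )
    nmi_table = pd.DataFrame(nmi_rows)
    q_table = pd.DataFrame(q_rows)

    test_seeds = iter(s_test.spawn(len(densities) * len(approaches) ** 2 * 2))
    test_rows = []
    for a1, a2 in combinations(approaches, 2):
        for score, table, col in (("nmi", nmi_table, "nmi"), ("modularity", q_table, "q")):
            for d in densities:
                va = table.query("approach == @a1 and density == @d")[col].to_numpy()
                vb = table.query("approach == @a2 and density == @d")[col].to_numpy()
                res = _signflip_test(
                    va, vb, n_iter, _seed_int(next(test_seeds)), "subject_count"
                )
                test_rows.append(
                    {
                        "pair": f"{a1}-{a2}",
                        "score": score,
                        "density": d,
                        "observed": res.observed,
                        "p_value": res.p_value,
                    }
                )
    tests = pd.DataFrame(test_rows)

    fdr = {}
    rejected = np.zeros(len(tests), dtype=bool)
    for (pair, score), grp in tests.groupby(["pair", "score"]):
        report = fdr_correct(grp["p_value"].to_numpy(), alpha=alpha)
        fdr[(pair, score)] = report
        rejected[grp.index] = report.rejected
    tests["rejected"] = rejected

    return ComparisonReport(nmi_table, q_table, tests, fdr, group_partitions)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
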