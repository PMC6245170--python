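"""Plain-text file formats.

Matrices are TSV floats without header (one row per node); partitions
are 2-column TSV (node_id, community_id) with an optional header; edge
lists are 3-column TSV (node_i, node_j, weight).  Node ids are 0-based
integers throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import ConnectivityMatrix, ThresholdedGraph, as_partition

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_edge_list",
    "write_provenance",
]

#: asymmetry up to this is silently fixed by averaging with the transpose
_ASYM_TOL = 1e-8


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "," if ("," in first and "\t" not in first) else "\t"


def read_matrix(path, scale: str | None = None) -> ConnectivityMatrix:
    """Read a square numeric TSV/CSV matrix.

    Asymmetry up to 1e-8 is repaired by averaging with the transpose;
    larger asymmetry is an error.  The diagonal is zeroed.  If ``scale``
    is None it is inferred: entries within [-1, 1] are treated as
    correlations, anything larger as Fisher-Z values.
    """
    path = Path(path)
    w = np.genfromtxt(path, delimiter=_sniff_delimiter(path))
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {w.shape}")
    if np.isnan(w).any():
        i, j = np.argwhere(np.isnan(w))[0]
        raise ValueError(f"{path}: NaN at row {i}, column {j}")
    asym = float(np.abs(w - w.T).max())
    if asym > _ASYM_TOL:
        raise ValueError(
            f"{path}: matrix is asymmetric (max |A - A.T| = {asym:.3g} "
            f"> {_ASYM_TOL:g})"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if scale is None:
        scale = "correlation" if np.abs(w).max(initial=0.0) <= 1.0 else "fisher_z"
    return ConnectivityMatrix(w, scale=scale)


def write_matrix(m: ConnectivityMatrix, path) -> None:
    np.savetxt(path, m.weights, delimiter="\t", fmt="%.17g")


def read_partition(path) -> np.ndarray:
    """Read a 2-column (node_id, community_id) TSV/CSV partition.

    A non-numeric first row is treated as a header.  Node ids must be
    exactly 0..n-1 with no duplicates; community labels are preserved
    verbatim.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty partition file")
    start = 0
    try:
        [float(x) for x in lines[0].split(delim)]
    except ValueError:
        start = 1  # header row
    rows = []
    for ln in lines[start:]:
        fields = ln.split(delim)
        if len(fields) != 2:
            raise ValueError(f"{path}: expected 2 columns, got {len(fields)}: {ln!r}")
        rows.append((int(fields[0]), int(fields[1])))
    nodes = np.array([r[0] for r in rows])
    labels = np.array([r[1] for r in rows])
    uniq, counts = np.unique(nodes, return_counts=True)
    dupes = uniq[counts > 1]
    if dupes.size:
        raise ValueError(f"{path}: duplicate node id(s) {dupes.tolist()}")
    expected = np.arange(len(rows))
    if not np.array_equal(np.sort(nodes), expected):
        missing = sorted(set(expected.tolist()) - set(nodes.tolist()))
        raise ValueError(f"{path}: node ids are not 0..{len(rows) - 1}; missing {missing}")
    out = np.empty(len(rows), dtype=np.int64)
    out[nodes] = labels
    return out


def write_partition(partition, path) -> None:
    p = as_partition(partition)
    with open(path, "w") as fh:
        fh.write("node_id\tcommunity_id\n")
        for node, label in enumerate(p):
            fh.write(f"{node}\t{int(label)}\n")


def write_edge_list(graph: ThresholdedGraph, path) -> None:
    with open(path, "w") as fh:
        for i, j, w in graph.edge_list():
            fh.write(f"{i}\t{j}\t{w:.17g}\n")


def write_provenance(path, **record) -> None:
    """JSON sidecar with everything needed to re-run a command."""
    from . import __version__

    record = {"netconsensus_version": __version__, **record}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
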