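"""From ROI time series to weighted undirected graphs.

Pipeline: (optional) resample + band-pass the ROI signals, Pearson
correlation matrix, Fisher-Z variance stabilization, proportional
density thresholding.  Thresholding ranks node pairs by *signed* weight
(anticorrelations are excluded first) and keeps the retained weights —
the graphs stay weighted, they are never binarized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .types import ConnectivityMatrix, ThresholdedGraph

__all__ = [
    "ROITimeSeries",
    "resample_and_filter",
    "correlation_matrix",
    "fisher_z",
    "edge_count",
    "threshold_by_density",
]

#: correlations are clipped to +/-(1 - _R_CLIP) before atanh
_R_CLIP = 1e-7


@dataclass(frozen=True)
class ROITimeSeries:
    """ROI x time signal matrix sampled at ``sampling_rate`` Hz."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (ROI x time), got shape {v.shape}")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(v).any():
            raise ValueError("time series contain NaN")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def resample_and_filter(
    ts: ROITimeSeries,
    discard_first: int = 4,
    up_rate: float = 1.0,
    band: tuple[float, float] = (0.01, 0.1),
    down_rate: float = 0.5,
) -> ROITimeSeries:
    """Discard initial volumes, up-sample, band-pass, down-sample.

    The first ``discard_first`` timepoints are dropped before anything
    else.  Up-sampling is linear interpolation onto a ``up_rate`` grid;
    the band-pass is a zero-phase 4th-order Butterworth (applied
    forward-backward, so no phase distortion); down-sampling keeps every
    ``up_rate / down_rate``-th filtered sample.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if high >= down_rate / 2:
        raise ValueError(
            f"band upper edge {high} Hz is at or above the output Nyquist "
            f"frequency {down_rate / 2} Hz"
        )
    if high >= up_rate / 2:
        raise ValueError(
            f"band upper edge {high} Hz is at or above the intermediate "
            f"Nyquist frequency {up_rate / 2} Hz"
        )
    if discard_first >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {discard_first} of {ts.n_timepoints} timepoints"
        )
    step = up_rate / down_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("up_rate must be an integer multiple of down_rate")
    step = int(round(step))

    x = ts.values[:, discard_first:]
    duration = (x.shape[1] - 1) / ts.sampling_rate
    t_orig = np.arange(x.shape[1]) / ts.sampling_rate
    t_up = np.arange(0.0, duration + 0.5 / up_rate, 1.0 / up_rate)
    up = np.vstack([np.interp(t_up, t_orig, row) for row in x])

    sos = _signal.butter(4, [low, high], btype="bandpass", fs=up_rate, output="sos")
    filtered = _signal.sosfiltfilt(sos, up, axis=1)
    return ROITimeSeries(filtered[:, ::step], sampling_rate=down_rate)


def correlation_matrix(ts) -> ConnectivityMatrix:
    """Pearson correlation of all ROI pairs, diagonal forced to zero."""
    values = ts.values if isinstance(ts, ROITimeSeries) else np.asarray(ts, dtype=float)
    sd = values.std(axis=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(
            f"ROI(s) {dead.tolist()} have zero variance; correlation undefined"
        )
    r = np.corrcoef(values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, scale="correlation")


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher-Z (atanh) transform of a correlation matrix.

    Off-diagonal |r| = 1 (duplicated signals) is clipped to
    1 - 1e-7 rather than mapped to infinity.
    """
    if m.scale != "correlation":
        raise ValueError(f"fisher_z expects correlation scale, got {m.scale!r}")
    r = np.clip(m.weights, -(1 - _R_CLIP), 1 - _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, scale="fisher_z")


def edge_count(n_nodes: int, density: float) -> int:
    """Number of retained edges: round-half-up of d * n(n-1)/2."""
    x = density * n_nodes * (n_nodes - 1) / 2.0
    # the 1e-9 guard keeps exact .5 products from falling just below the
    # boundary through floating-point representation of the density
    return int(math.floor(x + 0.5 + 1e-9))


def threshold_by_density(m: ConnectivityMatrix, density: float) -> ThresholdedGraph:
    """Keep the ``round(d * n(n-1)/2)`` strongest edges by signed weight.

    Ties at the boundary are broken by node-pair lexicographic order, so
    edge sets are nested across densities.  If the retained set reaches
    non-positive weights they are dropped with a warning: downstream
    modularity is defined for positive weights only.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = m.weights[iu, ju]
    k = edge_count(n, density)
    # stable sort by weight descending; triu_indices order is already
    # node-pair lexicographic, which the stable sort preserves for ties
    order = np.argsort(-w, kind="stable")[:k]
    keep_i, keep_j, keep_w = iu[order], ju[order], w[order]
    bad = keep_w <= 0
    if bad.any():
        warnings.warn(
            f"density {density:g} reaches {int(bad.sum())} non-positive "
            "weight(s); dropping them (modularity requires positive weights)",
            stacklevel=2,
        )
        keep_i, keep_j, keep_w = keep_i[~bad], keep_j[~bad], keep_w[~bad]
    adj = np.zeros((n, n))
    adj[keep_i, keep_j] = keep_w
    adj = adj + adj.T
    return ThresholdedGraph(adj, density=density)
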