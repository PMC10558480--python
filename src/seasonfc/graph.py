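"""Binary-graph topology of thresholded functional-connectivity matrices.

A subject's GM–GM, WM–WM and whole-brain (GM ∪ WM) correlation matrices
are thresholded at r = 0.2 and binarized; the resulting undirected graphs
are summarized by four metrics:

* density — present edges / possible edges, 2m / (N(N−1));
* transitivity — closed triplets / all triplets, tr(X³) / (Σᵢⱼ(X²)ᵢⱼ − tr(X²));
* global efficiency — mean of 1/dᵢⱼ over ordered node pairs (1/∞ = 0);
* characteristic path length — mean shortest-path length over mutually
  reachable unordered pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import FCMatrix, pearson_fc
from .signal import RegionTimeSeries

logger = logging.getLogger("seasonfc")

DEFAULT_THRESHOLD = 0.2


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(m) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.matrix = m.astype(np.int8)
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


@dataclass
class GraphMetrics:
    density: float
    transitivity: float
    global_efficiency: float
    characteristic_path_length: float


def threshold_binarize(
    fc: FCMatrix | np.ndarray,
    tau: float = DEFAULT_THRESHOLD,
    mode: str = "raw",
    labels: list[str] | None = None,
) -> AdjacencyMatrix:
    """Threshold a square symmetric correlation matrix into a binary graph.

    ``mode="raw"`` (default) keeps edges where r > tau, discarding negative
    correlations; ``mode="absolute"`` keeps |r| > tau. Thresholding is on
    correlation values, not Fisher-Z values. The diagonal is forced to 0.
    """
    if isinstance(fc, FCMatrix):
        values, labels = fc.values, list(fc.row_labels)
        if not fc.is_within_set:
            raise ValueError("graph construction needs a square within-set FC matrix")
    else:
        values = np.asarray(fc, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("graph construction needs a square matrix")
        labels = labels or [f"node_{i}" for i in range(values.shape[0])]
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("input matrix must be symmetric")
    values = (values + values.T) / 2.0
    if mode == "raw":
        adj = (values > tau).astype(np.int8)
    elif mode == "absolute":
        adj = (np.abs(values) > tau).astype(np.int8)
    else:
        raise ValueError("mode must be 'raw' or 'absolute'")
    np.fill_diagonal(adj, 0)
    return AdjacencyMatrix(adj, labels)


def density(adj: AdjacencyMatrix) -> float:
    """Fraction of possible undirected edges that are present."""
    n = adj.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return adj.n_edges / (n * (n - 1) / 2)


def transitivity(adj: AdjacencyMatrix, zero_denominator: str = "error") -> float:
    """Global clustering coefficient via the trace formula.

    Computed as tr(X³) / (Σᵢⱼ(X²)ᵢⱼ − tr(X²)): closed triplets over all
    connected triplets. A graph with no path of length two has no triplets;
    by default that raises, or returns 0 when ``zero_denominator="zero"``.
    """
    x = adj.matrix.astype(np.int64)
    x2 = x @ x
    denom = int(x2.sum() - np.trace(x2))
    if denom == 0:
        if zero_denominator == "zero":
            logger.info("transitivity: no connected triplets; returning 0 by config")
            return 0.0
        raise ValueError("no connected triplets; transitivity undefined")
    closed = int(np.trace(x2 @ x))
    return closed / denom


def shortest_path_matrix(adj: AdjacencyMatrix) -> np.ndarray:
    """Unweighted shortest-path lengths between all node pairs (∞ if unreachable)."""
    d = _csgraph_shortest_path(adj.matrix, method="D", unweighted=True, directed=False)
    return d


def global_efficiency(adj: AdjacencyMatrix) -> float:
    """Mean inverse shortest-path length over ordered pairs; 1/∞ = 0."""
    n = adj.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_path_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(adj: AdjacencyMatrix) -> float:
    """Mean shortest-path length over mutually reachable unordered pairs.

    Unreachable pairs are excluded from the average rather than treated as
    infinite, so the metric stays finite on disconnected graphs as long as
    at least one edge exists.
    """
    if adj.n_edges == 0:
        raise ValueError("graph has no edges; characteristic path length undefined")
    d = shortest_path_matrix(adj)
    iu = np.triu_indices(adj.n_nodes, k=1)
    pairs = d[iu]
    reachable = np.isfinite(pairs)
    return float(pairs[reachable].mean())


def graph_metrics(adj: AdjacencyMatrix, zero_denominator: str = "error") -> GraphMetrics:
    """All four topology metrics of one binary graph."""
    return GraphMetrics(
        density=density(adj),
        transitivity=transitivity(adj, zero_denominator=zero_denominator),
        global_efficiency=global_efficiency(adj),
        characteristic_path_length=characteristic_path_length(adj),
    )


#: Square matrix kinds analyzed per subject.
MATRIX_KINDS = ("gm_gm", "wm_wm", "union")


def square_fc_matrices(series: RegionTimeSeries) -> dict[str, FCMatrix]:
    """GM–GM, WM–WM and whole-brain (GM ∪ WM) correlation matrices.

    The union matrix contains the two within-tissue blocks on its diagonal
    and the GM–WM cross-correlations off-diagonal.
    """
    gm = series.select_tissue("GM")
    wm = series.select_tissue("WM")
    return {
        "gm_gm": pearson_fc(gm, gm),
        "wm_wm": pearson_fc(wm, wm),
        "union": pearson_fc(series, series),
    }


def graph_metrics_for_subject(
    subject,
    tau: float = DEFAULT_THRESHOLD,
    mode: str = "raw",
    zero_denominator: str = "error",
) -> dict[str, GraphMetrics]:
    """Per-matrix-kind topology metrics for one subject.

    ``subject`` may be a cohort subject record or a bare
    :class:`~seasonfc.signal.RegionTimeSeries` of filtered, normalized
    signals.
    """
    series: RegionTimeSeries = getattr(subject, "series", subject)
    out: dict[str, GraphMetrics] = {}
    for kind, fc in square_fc_matrices(series).items():
        adj = threshold_binarize(fc, tau=tau, mode=mode)
        out[kind] = graph_metrics(adj, zero_denominator=zero_denominator)
    return out
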