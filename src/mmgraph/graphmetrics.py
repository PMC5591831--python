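"""Raw and null-normalized small-world metrics.

For a binary graph the mean Watts-Strogatz clustering coefficient C and
the characteristic path length L are normalized by their means over an
ensemble of degree-preserving random references (double-edge-swap /
Maslov-Sneppen rewiring):

    gamma = C / C_rand,   lambda = L / L_rand,   sigma = gamma / lambda.

sigma > 1 indicates small-world organization: lattice-like clustering with
random-like path lengths.  One shared null ensemble per graph serves both
normalizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from . import _fast
from .connectivity import BinaryGraph, ConnectivityMatrix, binarize_over_grid

__all__ = [
    "GraphMetrics",
    "SmallWorldCurve",
    "clustering_coefficient",
    "characteristic_path_length",
    "random_reference",
    "normalized_metrics",
    "metrics_over_sparsity",
    "node_gamma_summary",
]


def _adjacency(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(graph, BinaryGraph):
        return graph.adjacency  # validated (or trusted) at construction
    a = np.asarray(graph)
    return BinaryGraph(adjacency=a, sparsity=np.nan).adjacency


def clustering_coefficient(graph: BinaryGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node and mean clustering coefficient.

    node_C(i) = 2 t(i) / (k_i (k_i - 1)) where t(i) counts triangles through
    node i; nodes of degree < 2 get 0.  C is the unweighted node mean.
    """
    node_c = _fast.local_clustering(_adjacency(graph))
    return node_c, float(node_c.mean())


def characteristic_path_length(
    graph: BinaryGraph | np.ndarray, *, mode: str = "reachable"
) -> tuple[float, bool]:
    """Mean shortest-path length and a fragmentation flag.

    ``mode="reachable"`` (default) averages BFS distances over all
    reachable ordered pairs, excluding unreachable ones and setting
    ``fragmented=True`` when any pair is unreachable.  ``mode="efficiency"``
    returns the harmonic-mean alternative 1 / mean(1/d) with unreachable
    pairs contributing zero efficiency.
    """
    adj = _adjacency(graph)
    if adj.shape[0] < 2:
        raise ValueError("path length needs at least 2 nodes")
    if adj.sum() == 0:
        raise ValueError("path length undefined for a graph with no edges")
    if mode == "reachable":
        L, n_unreach = _fast.bfs_mean_path(adj)
        return float(L), bool(n_unreach > 0)
    if mode == "efficiency":
        d = shortest_path(csr_matrix(adj), method="D", unweighted=True)
        off = ~np.eye(adj.shape[0], dtype=bool)
        inv = np.zeros_like(d)
        finite = np.isfinite(d) & (d > 0)
        inv[finite] = 1.0 / d[finite]
        eff = inv[off].mean()
        return float(1.0 / eff), bool(np.isinf(d[off]).any())
    raise ValueError("mode must be 'reachable' or 'efficiency'")


def random_reference(
    graph: BinaryGraph | np.ndarray,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> tuple[BinaryGraph, int]:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``swaps_per_edge * |E|`` swaps; attempts that would create a
    self-loop or multi-edge are skipped.  Returns the rewired graph and the
    number of successful swaps (0 means no legal swap existed and the input
    came back unchanged, e.g. for a triangle).
    """
    adj = _adjacency(graph)
    n_edges = int(adj.sum()) // 2
    rewired, n_success = _fast.double_edge_swap(
        adj, int(swaps_per_edge) * n_edges, int(seed)
    )
    sparsity = graph.sparsity if isinstance(graph, BinaryGraph) else np.nan
    return BinaryGraph(adjacency=rewired, sparsity=sparsity), int(n_success)


@dataclass
class GraphMetrics:
    """Raw and null-normalized metrics of one binary graph."""

    C: float
    node_C: np.ndarray
    L: float
    C_rand: float
    L_rand: float
    gamma: float
    lam: float
    sigma: float
    n_null: int
    fragmented: bool
    sparsity: float
    C_rand_sd: float = np.nan
    L_rand_sd: float = np.nan
    node_C_rand: np.ndarray | None = None


def normalized_metrics(
    graph: BinaryGraph | np.ndarray,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> GraphMetrics:
    """Metrics of ``graph`` normalized by a random-reference ensemble.

    C_rand and L_rand are means over ``n_null`` independent degree-preserving
    randomizations (ensemble member j seeded ``seed + j``); ensemble SDs are
    stored for diagnostics.  A degenerate null family with zero mean
    clustering makes gamma undefined and raises.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    adj = _adjacency(graph)
    if adj.shape[0] < 2 or adj.sum() == 0:
        raise ValueError("normalized metrics need >= 2 nodes and >= 1 edge")
    node_c = _fast.local_clustering(adj)
    C = float(node_c.mean())
    L, n_unreach = _fast.bfs_mean_path(adj)
    L = float(L)
    fragmented = bool(n_unreach > 0)
    node_c_rand, c_null, l_null, _n_frag, _ = _fast.null_ensemble(
        adj, int(n_null), int(swaps_per_edge), int(seed)
    )
    C_rand = float(c_null.mean())
    L_rand = float(np.nanmean(l_null))
    if C_rand == 0.0:
        raise ValueError(
            "null ensemble has zero mean clustering; gamma undefined for "
            "this degree sequence (e.g. trees/stars admit no triangles)"
        )
    gamma = C / C_rand
    lam = L / L_rand
    return GraphMetrics(
        C=C,
        node_C=node_c,
        L=L,
        C_rand=C_rand,
        L_rand=L_rand,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        n_null=int(n_null),
        fragmented=bool(fragmented),
        sparsity=float(graph.sparsity) if isinstance(graph, BinaryGraph) else np.nan,
        C_rand_sd=float(c_null.std(ddof=1)) if n_null > 1 else np.nan,
        L_rand_sd=float(np.nanstd(l_null, ddof=1)) if n_null > 1 else np.nan,
        node_C_rand=node_c_rand,
    )


@dataclass
class SmallWorldCurve:
    """Per-sparsity metrics for one recording (one band, one modality)."""

    sparsity: np.ndarray
    metrics: list[GraphMetrics]
    subject_id: str = ""
    group: str | None = None
    modality: str = ""
    band: str | None = None
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sparsity) != len(self.metrics):
            raise ValueError("one GraphMetrics entry per sparsity level required")

    def values(self, metric: str) -> np.ndarray:
        """Vector of one scalar metric (gamma|lam|sigma|C|L|...) over the grid."""
        return np.array([getattr(m, metric) for m in self.metrics], dtype=float)

    @property
    def fragmented_levels(self) -> np.ndarray:
        return np.array([m.fragmented for m in self.metrics], dtype=bool)


def metrics_over_sparsity(
    cmatrix: ConnectivityMatrix,
    grid: np.ndarray | None = None,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    *,
    band: str | None = None,
    edge_strength: str = "absolute",
) -> SmallWorldCurve:
    """Binarize over the sparsity grid and normalize metrics at each level.

    Null ensembles at different levels use disjoint seed blocks
    (``seed + level_index * n_null``) so curves are reproducible and
    ensemble members never repeat across levels.
    """
    graphs = binarize_over_grid(cmatrix, grid, edge_strength=edge_strength)
    out = []
    for li, g in enumerate(graphs):
        out.append(
            normalized_metrics(
                g, n_null=n_null, swaps_per_edge=swaps_per_edge,
                seed=seed + li * n_null,
            )
        )
    return SmallWorldCurve(
        sparsity=np.array([g.sparsity for g in graphs]),
        metrics=out,
        subject_id=cmatrix.subject_id,
        group=cmatrix.group,
        modality=cmatrix.modality,
        band=band,
        node_labels=list(cmatrix.node_labels),
    )


def node_gamma_summary(
    curve: SmallWorldCurve, *, aggregation: str = "pooled"
) -> tuple[np.ndarray, np.ndarray]:
    """One normalized-clustering scalar per node for one recording.

    Summarizes a node's clustering across the sparsity grid relative to
    the null ensembles.  ``aggregation="pooled"`` (default) divides the
    node's clustering summed over levels by its null-mean clustering
    summed over the same levels — a ratio of means, stable even at sparse
    levels where a single null mean is close to zero.
    ``aggregation="per_level"`` instead averages the per-level ratios
    node_C(i)/null_node_C(i) over the levels with a positive null mean;
    it weights all levels equally but has heavy-tailed noise at sparse
    levels.  Nodes with no usable level (e.g. isolated everywhere, so no
    reference can form a triangle) get NaN and are flagged.

    Returns (node_gamma, undefined_mask).
    """
    if aggregation not in ("pooled", "per_level"):
        raise ValueError("aggregation must be 'pooled' or 'per_level'")
    n = len(curve.metrics[0].node_C)
    for m in curve.metrics:
        if m.node_C_rand is None:
            raise ValueError("curve lacks per-node null clustering means")
    obs = np.array([m.node_C for m in curve.metrics])  # levels × nodes
    null = np.array([m.node_C_rand for m in curve.metrics])
    usable = null > 0
    undefined = ~usable.any(axis=0)
    node_gamma = np.full(n, np.nan)
    if aggregation == "pooled":
        num = np.where(usable, obs, 0.0).sum(axis=0)
        den = np.where(usable, null, 0.0).sum(axis=0)
        ok = ~undefined
        node_gamma[ok] = num[ok] / den[ok]
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(usable, obs / null, np.nan)
        node_gamma[~undefined] = np.nanmean(ratios, axis=0)[~undefined]
    return node_gamma, undefined
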