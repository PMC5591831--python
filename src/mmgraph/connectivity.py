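"""Association matrices and sparsity-thresholded binary graphs.

Connectivity is Pearson correlation between node time series (optionally
Fisher-z transformed for export; z is monotone in r, so binarized graphs
are identical either way).  Binarization fixes the *sparsity* S — the
fraction of possible edges retained — rather than an absolute threshold,
which equalizes edge count across subjects before comparing topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .containers import TimeSeriesMatrix, as_node_labels

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "default_sparsity_grid",
    "correlation_matrix",
    "fisher_z",
    "threshold_by_sparsity",
    "binarize_over_grid",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric node × node association matrix with zero diagonal."""

    values: np.ndarray
    scale: str = "pearson_r"  # pearson_r | fisher_z
    n_samples_used: int = 0
    modality: str = ""
    subject_id: str = ""
    group: str | None = None
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("connectivity diagonal must be zero")
        if self.scale == "pearson_r" and np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError("pearson_r entries must lie in [-1, 1]")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError("scale must be 'pearson_r' or 'fisher_z'")
        self.values = v
        self.node_labels = as_node_labels(self.node_labels or None, v.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected 0/1 adjacency at a given realized sparsity."""

    adjacency: np.ndarray
    sparsity: float
    source_threshold: float = np.nan
    connected: bool | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.any(np.diag(a) != 0) or not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @classmethod
    def _unchecked(
        cls,
        adjacency: np.ndarray,
        sparsity: float,
        source_threshold: float,
        connected: bool | None,
    ) -> "BinaryGraph":
        # fast path for adjacencies that are 0/1 symmetric by construction
        g = cls.__new__(cls)
        g.adjacency = adjacency
        g.sparsity = sparsity
        g.source_threshold = source_threshold
        g.connected = connected
        return g


def default_sparsity_grid() -> np.ndarray:
    """The analysis grid 0.11 ≤ S ≤ 0.45 in steps of 0.01 (35 levels)."""
    return np.round(np.arange(11, 46) / 100.0, 2)


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation of every channel pair, diagonal forced to zero."""
    if ts.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    sd = ts.values.std(axis=1)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        names = [ts.node_labels[i] for i in constant]
        raise ValueError(
            f"constant channel(s) make correlation undefined: {names}"
        )
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        values=r,
        scale="pearson_r",
        n_samples_used=ts.n_samples,
        modality=ts.modality,
        subject_id=ts.subject_id,
        group=ts.group,
        node_labels=list(ts.node_labels),
    )


def fisher_z(cmatrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise Fisher transform z = arctanh(r); diagonal stays zero.

    Off-diagonal |r| = 1 (which would map to infinity) is clipped to
    1 - 1e-7 with a warning.
    """
    if cmatrix.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    r = cmatrix.values.copy()
    lim = 1.0 - 1e-7
    mask = np.abs(r) >= lim
    np.fill_diagonal(mask, False)
    if mask.any():
        warnings.warn(
            f"{int(mask.sum()) // 2} correlation(s) at |r| >= 1 clipped to "
            f"+/-{lim} before the Fisher transform",
            stacklevel=2,
        )
        r[mask] = np.sign(r[mask]) * lim
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z,
        scale="fisher_z",
        n_samples_used=cmatrix.n_samples_used,
        modality=cmatrix.modality,
        subject_id=cmatrix.subject_id,
        group=cmatrix.group,
        node_labels=list(cmatrix.node_labels),
    )


def _ranked_edges(cmatrix: ConnectivityMatrix, edge_strength: str):
    """Upper-triangle edges ordered by decreasing strength.

    Ties break deterministically by (min-node, max-node) lexicographic
    index, so every run selects identical edge sets.
    """
    n = cmatrix.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    if edge_strength == "absolute":
        strength = np.abs(cmatrix.values[iu, ju])
    elif edge_strength == "positive":
        strength = cmatrix.values[iu, ju].copy()
    else:
        raise ValueError("edge_strength must be 'absolute' or 'positive'")
    order = np.lexsort((ju, iu, -strength))
    return iu[order], ju[order], strength[order]


def threshold_by_sparsity(
    cmatrix: ConnectivityMatrix,
    S: float,
    *,
    edge_strength: str = "absolute",
) -> BinaryGraph:
    """Keep exactly round(S · N(N−1)/2) strongest edges as a binary graph.

    Edge strength defaults to the absolute association (negative
    correlations count by magnitude); ``edge_strength="positive"`` ranks
    signed values instead.  If fewer nonzero strengths exist than
    requested, all of them are kept and the realized sparsity is reported
    with a warning.
    """
    if not (0.0 < S <= 1.0):
        raise ValueError(f"sparsity S must lie in (0, 1], got {S}")
    n = cmatrix.n_nodes
    max_edges = n * (n - 1) // 2
    m = int(round(S * max_edges))
    ii, jj, strength = _ranked_edges(cmatrix, edge_strength)
    n_nonzero = int((strength > 0).sum())
    if m > n_nonzero:
        warnings.warn(
            f"sparsity {S} requests {m} edges but only {n_nonzero} nonzero "
            f"strengths exist; realized sparsity {n_nonzero / max_edges:.4f}",
            stacklevel=2,
        )
        m = n_nonzero
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:m], jj[:m]] = 1
    adj |= adj.T
    cut = float(strength[m - 1]) if m > 0 else np.nan
    return BinaryGraph(
        adjacency=adj,
        sparsity=m / max_edges,
        source_threshold=cut,
        connected=bool(_fast.n_components(adj) == 1),
    )


def binarize_over_grid(
    cmatrix: ConnectivityMatrix,
    grid: np.ndarray | None = None,
    *,
    edge_strength: str = "absolute",
) -> list[BinaryGraph]:
    """One binary graph per sparsity level of the grid.

    Because every level keeps a prefix of the same strength ranking, the
    edge sets are nested (S1 < S2 implies edges(S1) ⊆ edges(S2)).
    """
    if grid is None:
        grid = default_sparsity_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be a nonempty increasing vector")
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("sparsity levels must lie in (0, 1]")
    # rank once; every level keeps a prefix of the same ordering
    n = cmatrix.n_nodes
    max_edges = n * (n - 1) // 2
    ii, jj, strength = _ranked_edges(cmatrix, edge_strength)
    n_nonzero = int((strength > 0).sum())
    adj = np.zeros((n, n), dtype=np.uint8)
    out: list[BinaryGraph] = []
    m_prev = 0
    for S in grid:
        m = int(round(S * max_edges))
        if m > n_nonzero:
            warnings.warn(
                f"sparsity {S} requests {m} edges but only {n_nonzero} nonzero "
                f"strengths exist; realized sparsity {n_nonzero / max_edges:.4f}",
                stacklevel=2,
            )
            m = n_nonzero
        sl = slice(m_prev, m)
        adj[ii[sl], jj[sl]] = 1
        adj[jj[sl], ii[sl]] = 1
        m_prev = max(m, m_prev)
        level = adj.copy()
        out.append(
            BinaryGraph._unchecked(
                adjacency=level,
                sparsity=m / max_edges,
                source_threshold=float(strength[m - 1]) if m > 0 else np.nan,
                connected=bool(_fast.n_components(level) == 1),
            )
        )
    return out
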