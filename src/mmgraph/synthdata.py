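"""Synthetic ground-truth graphs, recordings and cohorts.

The study design this module emulates: patients are recorded twice
(R1 before and R2 immediately after a 1 Hz rTMS session) together with a
once-recorded healthy-control group (HC), simultaneously in two modalities
(31-channel scalp EEG and 160-ROI resting-state fMRI).

Each subject owns a Watts-Strogatz small-world graph.  Signals are
stationary multivariate Gaussians whose covariance is ``I + W`` where the
weight ``W`` places coupling on the planted edges, so that Pearson
correlation of the generated time series recovers the planted topology.
The group effect is planted on the *within-cluster* edges (edges that
close at least one triangle):

* HC keeps full coupling ``c`` on every edge,
* R1 has within-cluster coupling reduced to ``c * (1 - clustering_deficit)``
  on every triangle edge (the disease-induced, spatially broad loss of
  clustered connectivity),
* R2 rescales the within-cluster coupling by ``(1 + boost_s)`` relative to
  R1, but only on triangle edges touching a fixed *affected* subset of
  nodes (fraction ``effect_fraction`` of the ring, the same nodes in every
  subject, emulating an anatomically consistent stimulation site).
  ``boost_s`` is the subject's individual response, drawn once per subject
  around ``clustering_boost`` with SD ``boost_sd`` and shared between the
  EEG and fMRI recordings — so post-stimulation change scores of affected
  nodes co-vary across modalities, which is what the cross-modal analysis
  looks for.

The deficit is broad, so group-level curves show R1 below HC; the recovery
is focal and subject-variable, so node-level statistics single out the
affected regions and cross-modal correlations of the change scores emerge
there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import TimeSeriesMatrix

__all__ = [
    "GroundTruthGraph",
    "SyntheticCohortSpec",
    "Cohort",
    "generate_small_world_graph",
    "covariance_from_graph",
    "covariance_from_weights",
    "generate_subject_timeseries",
    "generate_cohort",
]

_NETWORK_NAMES = (
    "cerebellar",
    "cingulo-opercular",
    "default",
    "fronto-parietal",
    "sensorimotor",
    "occipital",
)


@dataclass(frozen=True)
class GroundTruthGraph:
    """A planted small-world topology (ring lattice with rewired edges)."""

    adjacency: np.ndarray
    n_nodes: int
    ring_degree: int
    rewire_prob: float
    seed: int

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def generate_small_world_graph(
    n_nodes: int, k: int, p_rewire: float, seed: int
) -> GroundTruthGraph:
    """Watts-Strogatz graph: ring lattice of even degree ``k`` with each
    edge rewired independently with probability ``p_rewire``.

    Rewiring replaces one endpoint, so the edge count ``n_nodes * k / 2``
    is conserved for every ``p_rewire``.  At ``p_rewire = 0`` every node has
    degree exactly ``k`` and the mean clustering equals the lattice
    closed form ``3 (k - 2) / (4 (k - 1))``.
    """
    if k % 2 != 0:
        raise ValueError(f"ring degree k must be even, got {k}")
    if not (2 <= k < n_nodes):
        raise ValueError(f"need n_nodes > k >= 2, got n_nodes={n_nodes}, k={k}")
    if not (0.0 <= p_rewire <= 1.0):
        raise ValueError(f"p_rewire must lie in [0, 1], got {p_rewire}")
    g = nx.watts_strogatz_graph(n_nodes, k, p_rewire, seed=seed)
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=np.uint8)
    return GroundTruthGraph(
        adjacency=adj,
        n_nodes=n_nodes,
        ring_degree=k,
        rewire_prob=p_rewire,
        seed=seed,
    )


def covariance_from_weights(weights: np.ndarray) -> np.ndarray:
    """Covariance ``Σ = I + W`` for a symmetric zero-diagonal weight matrix.

    Fails if the result is not positive definite (coupling too strong for
    the graph's spectrum).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError("weights must have a zero diagonal")
    sigma = np.eye(w.shape[0]) + w
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig <= 1e-10:
        raise ValueError(
            "covariance I + W is not positive definite "
            f"(smallest eigenvalue {min_eig:.3g}); reduce the coupling "
            "strength below 1/|lambda_min| of the weighted adjacency"
        )
    return sigma


def covariance_from_graph(
    graph: GroundTruthGraph | np.ndarray, coupling_strength: float
) -> np.ndarray:
    """Covariance ``Σ = I + c A`` for a planted adjacency ``A``.

    Off-diagonal entries are ``c`` for adjacent pairs and 0 otherwise, so
    Pearson correlation of draws from ``Σ`` separates planted edges from
    non-edges.  ``c`` must keep ``Σ`` positive definite (``c < 1/|λ_min(A)|``).
    """
    adj = graph.adjacency if isinstance(graph, GroundTruthGraph) else np.asarray(graph)
    if coupling_strength < 0:
        raise ValueError("coupling_strength must be nonnegative")
    return covariance_from_weights(coupling_strength * adj.astype(float))


def generate_subject_timeseries(
    covariance: np.ndarray,
    n_samples: int,
    sampling_rate: float,
    modality: str,
    seed: int | np.random.SeedSequence,
    *,
    ar_coeff: float = 0.0,
    subject_id: str = "",
    group: str | None = None,
    node_labels: list[str] | None = None,
) -> TimeSeriesMatrix:
    """Stationary multivariate Gaussian recording with the given covariance.

    By default samples are temporally i.i.d. (the downstream analyses act
    only on Pearson correlation, which this suffices to exercise).  With
    ``0 < ar_coeff < 1`` each channel additionally carries an AR(1) factor,
    scaled so the stationary covariance is unchanged — useful for testing
    the temporal filters on non-white input.
    """
    cov = np.asarray(covariance, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    if not (0.0 <= ar_coeff < 1.0):
        raise ValueError("ar_coeff must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((cov.shape[0], n_samples))
    if ar_coeff > 0.0:
        # AR(1) innovations scaled to keep unit stationary variance
        z = lfilter([np.sqrt(1.0 - ar_coeff**2)], [1.0, -ar_coeff], z, axis=1)
    values = chol @ z
    return TimeSeriesMatrix(
        values=values,
        sampling_rate=sampling_rate,
        modality=modality,
        subject_id=subject_id,
        group=group,
        node_labels=node_labels or [],
    )


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Counts mirror the emulated study: 14 patients recorded before (R1) and
    after (R2) stimulation, 20 once-recorded healthy controls, 31 EEG
    channels and 160 fMRI ROIs.  EEG is emitted at 250 Hz for the recorded
    protocol length (185 3-s dynamics); fMRI at TR = 3 s.

    ``clustering_deficit`` scales down within-cluster (triangle-edge)
    coupling in patients relative to HC.  ``clustering_boost`` is the mean
    stimulation response: R2 rescales within-cluster coupling by
    ``1 + boost`` relative to R1 (1.0 = doubling) on triangle edges
    touching the affected node subset (``effect_fraction`` of the nodes);
    each subject's individual boost is drawn with SD ``boost_sd`` and
    shared across modalities.  ``noise_sd`` is additive white sensor noise
    relative to unit signal variance.
    """

    n_paired_subjects: int = 14
    n_hc_subjects: int = 20
    n_eeg_channels: int = 31
    n_fmri_rois: int = 160
    eeg_samples: int = 138_750  # 185 dynamics x 3 s x 250 Hz
    eeg_sampling_rate: float = 250.0
    fmri_volumes: int = 180
    fmri_tr_s: float = 3.0
    ring_degree_eeg: int = 6
    ring_degree_fmri: int = 12
    rewire_prob: float = 0.1
    coupling_eeg: float = 0.22
    coupling_fmri: float = 0.15
    clustering_deficit: float = 0.5
    clustering_boost: float = 0.8
    boost_sd: float = 0.4
    effect_fraction: float = 0.25
    noise_sd: float = 0.5
    ar_coeff: float = 0.0
    seed: int = 0
    modalities: tuple[str, ...] = ("eeg", "fmri")

    def __post_init__(self) -> None:
        counts = {
            "n_paired_subjects": self.n_paired_subjects,
            "n_hc_subjects": self.n_hc_subjects,
            "n_eeg_channels": self.n_eeg_channels,
            "n_fmri_rois": self.n_fmri_rois,
            "eeg_samples": self.eeg_samples,
            "fmri_volumes": self.fmri_volumes,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.clustering_boost < 0:
            raise ValueError("clustering_boost must be nonnegative")
        if self.boost_sd < 0:
            raise ValueError("boost_sd must be nonnegative")
        if not (0.0 <= self.clustering_deficit < 1.0):
            raise ValueError("clustering_deficit must lie in [0, 1)")
        if not (0.0 < self.effect_fraction <= 1.0):
            raise ValueError("effect_fraction must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.modalities) - {"eeg", "fmri"}
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")


@dataclass
class Cohort:
    """A generated study dataset: recordings plus manifest and node tables."""

    spec: SyntheticCohortSpec
    manifest: pd.DataFrame
    recordings: dict[str, TimeSeriesMatrix]
    node_tables: dict[str, pd.DataFrame]
    graphs: dict[str, GroundTruthGraph] = field(default_factory=dict)

    def get(self, subject_id: str, group: str, modality: str) -> TimeSeriesMatrix:
        rid = f"{subject_id}_{group}_{modality}"
        return self.recordings[rid]


def _triangle_edge_mask(adj: np.ndarray) -> np.ndarray:
    """Boolean mask of edges that participate in at least one triangle."""
    a = adj.astype(float)
    common = a @ a  # common-neighbour counts
    return (adj > 0) & (common > 0)


def _group_weights(
    adj: np.ndarray,
    coupling: float,
    deficit: float,
    boost: float,
    session: str,
    affected: np.ndarray,
) -> np.ndarray:
    """Per-edge coupling for one group/session on a subject's graph.

    ``affected`` is a boolean node mask; in R2, triangle edges with at
    least one affected endpoint carry the subject's boost.
    """
    w = coupling * adj.astype(float)
    tri = _triangle_edge_mask(adj)
    if session == "HC":
        return w
    w[tri] *= 1.0 - deficit
    if session == "R2":
        touched = tri & (affected[:, None] | affected[None, :])
        w[touched] *= 1.0 + boost
    return w


def _electrode_table(n: int) -> pd.DataFrame:
    """Synthetic scalp positions: spiral points on the upper hemisphere of a
    90 mm head sphere (deterministic; not a montage of any real cap)."""
    idx = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = idx / max(n - 1, 1)  # hemisphere: z in [0, 1]
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = golden * idx
    pts = 90.0 * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pd.DataFrame(
        {
            "label": [f"EEG{i + 1:02d}" for i in idx],
            "x_mm": np.round(pts[:, 0], 1),
            "y_mm": np.round(pts[:, 1], 1),
            "z_mm": np.round(pts[:, 2], 1),
            "network": "scalp",
        }
    )


def _roi_table(n: int, seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """Synthetic ROI centres drawn once per cohort inside a brain-sized box."""
    rng = np.random.default_rng(seed_seq)
    xyz = rng.uniform([-70, -100, -60], [70, 70, 80], size=(n, 3))
    return pd.DataFrame(
        {
            "label": [f"ROI{i + 1:03d}" for i in range(n)],
            "x_mm": np.round(xyz[:, 0], 1),
            "y_mm": np.round(xyz[:, 1], 1),
            "z_mm": np.round(xyz[:, 2], 1),
            "network": [_NETWORK_NAMES[i % len(_NETWORK_NAMES)] for i in range(n)],
        }
    )


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate the full multi-group, multi-modal study dataset.

    One master seed drives everything; per-subject/per-session sub-streams
    are spawned deterministically, so a fixed spec is bit-reproducible.
    R1 and R2 recordings of one subject share that subject's planted graph
    (independent noise), HC subjects draw fresh graphs from the same family.
    """
    master = np.random.SeedSequence(spec.seed)
    ss_rois, ss_subjects = master.spawn(2)

    node_tables: dict[str, pd.DataFrame] = {}
    if "eeg" in spec.modalities:
        node_tables["eeg"] = _electrode_table(spec.n_eeg_channels)
    if "fmri" in spec.modalities:
        node_tables["fmri"] = _roi_table(spec.n_fmri_rois, ss_rois)

    mod_conf = {
        "eeg": (
            spec.n_eeg_channels,
            spec.ring_degree_eeg,
            spec.coupling_eeg,
            spec.eeg_samples,
            spec.eeg_sampling_rate,
        ),
        "fmri": (
            spec.n_fmri_rois,
            spec.ring_degree_fmri,
            spec.coupling_fmri,
            spec.fmri_volumes,
            1.0 / spec.fmri_tr_s,
        ),
    }

    subjects = [(f"WC{i + 1:02d}", ("R1", "R2")) for i in range(spec.n_paired_subjects)]
    subjects += [(f"HC{i + 1:02d}", ("HC",)) for i in range(spec.n_hc_subjects)]

    recordings: dict[str, TimeSeriesMatrix] = {}
    graphs: dict[str, GroundTruthGraph] = {}
    rows = []
    sub_streams = ss_subjects.spawn(len(subjects))
    for (subject_id, sessions), ss_sub in zip(subjects, sub_streams):
        ss_eeg, ss_fmri, ss_boost = ss_sub.spawn(3)
        mod_streams = {"eeg": ss_eeg, "fmri": ss_fmri}
        # individual stimulation response, shared across modalities.
        # Capped at full restoration of the healthy coupling,
        # (1 - deficit) * (1 + boost) <= 1, which also keeps the R2
        # covariance inside the positive-definite region established for HC.
        cap = (
            spec.clustering_deficit / (1.0 - spec.clustering_deficit)
            if spec.clustering_deficit > 0
            else 0.0
        )
        raw = np.random.default_rng(ss_boost).normal(
            spec.clustering_boost, spec.boost_sd
        )
        boost_s = float(np.clip(raw, 0.0, cap))
        for modality in spec.modalities:
            n_nodes, k, coupling, n_samples, rate = mod_conf[modality]
            affected = np.zeros(n_nodes, dtype=bool)
            affected[: max(1, round(spec.effect_fraction * n_nodes))] = True
            ss_mod = mod_streams[modality]
            graph_seed = int(ss_mod.generate_state(1, np.uint32)[0] >> 1)
            graph = generate_small_world_graph(n_nodes, k, spec.rewire_prob, graph_seed)
            graphs[f"{subject_id}_{modality}"] = graph
            session_streams = ss_mod.spawn(len(sessions))
            for session, ss_sess in zip(sessions, session_streams):
                w = _group_weights(
                    graph.adjacency,
                    coupling,
                    spec.clustering_deficit,
                    boost_s,
                    session,
                    affected,
                )
                cov = covariance_from_weights(w)
                ss_signal, ss_noise = ss_sess.spawn(2)
                ts = generate_subject_timeseries(
                    cov,
                    n_samples,
                    rate,
                    modality,
                    ss_signal,
                    ar_coeff=spec.ar_coeff,
                    subject_id=subject_id,
                    group=session,
                    node_labels=list(node_tables[modality]["label"]),
                )
                noise = np.random.default_rng(ss_noise).standard_normal(
                    ts.values.shape
                )
                ts.values += spec.noise_sd * noise
                rid = f"{subject_id}_{session}_{modality}"
                recordings[rid] = ts
                rows.append(
                    {
                        "recording_id": rid,
                        "subject_id": subject_id,
                        "group": session,
                        "modality": modality,
                        "pair_id": subject_id if session != "HC" else "",
                    }
                )
    manifest = pd.DataFrame(rows)
    return Cohort(
        spec=spec,
        manifest=manifest,
        recordings=recordings,
        node_tables=node_tables,
        graphs=graphs,
    )
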