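"""On-disk formats: delimited numeric matrices with JSON sidecars.

Every recording persists as a plain TSV (nodes × samples, no header) next
to a ``<name>.json`` sidecar holding modality, sampling rate, units, group
and node labels.  Connectivity matrices and binary graphs follow the same
pattern; cohorts add a ``manifest.tsv`` and per-modality node tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BinaryGraph, ConnectivityMatrix
from .containers import TimeSeriesMatrix
from .synthdata import Cohort, SyntheticCohortSpec

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_connectivity",
    "read_connectivity",
    "write_graph",
    "read_graph",
    "write_cohort",
    "read_cohort",
    "read_edf",
    "read_nifti_voxels",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.10g")
    meta = {
        "kind": "timeseries",
        "modality": ts.modality,
        "sampling_rate_hz": ts.sampling_rate,
        "units": "uV" if ts.modality == "eeg" else "au",
        "subject_id": ts.subject_id,
        "group": ts.group,
        "node_labels": ts.node_labels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return TimeSeriesMatrix(
        values=values,
        sampling_rate=meta["sampling_rate_hz"],
        modality=meta["modality"],
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group"),
        node_labels=meta.get("node_labels", []),
    )


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, cm.values, delimiter="\t", fmt="%.12g")
    meta = {
        "kind": "connectivity",
        "scale": cm.scale,
        "n_samples_used": cm.n_samples_used,
        "modality": cm.modality,
        "subject_id": cm.subject_id,
        "group": cm.group,
        "node_labels": cm.node_labels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return ConnectivityMatrix(
        values=np.loadtxt(path, delimiter="\t", ndmin=2),
        scale=meta["scale"],
        n_samples_used=meta.get("n_samples_used", 0),
        modality=meta.get("modality", ""),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group"),
        node_labels=meta.get("node_labels", []),
    )


def write_graph(graph: BinaryGraph, path: str | Path) -> Path:
    """Edge list (TSV: node_i, node_j, 0-based) plus sparsity sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ii, jj = np.nonzero(np.triu(graph.adjacency, k=1))
    pd.DataFrame({"node_i": ii, "node_j": jj}).to_csv(path, sep="\t", index=False)
    meta = {
        "kind": "binary_graph",
        "n_nodes": graph.n_nodes,
        "sparsity": graph.sparsity,
        "source_threshold": None
        if np.isnan(graph.source_threshold)
        else graph.source_threshold,
        "connected": graph.connected,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_graph(path: str | Path) -> BinaryGraph:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    edges = pd.read_csv(path, sep="\t")
    n = meta["n_nodes"]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[edges["node_i"], edges["node_j"]] = 1
    adj |= adj.T
    thr = meta.get("source_threshold")
    return BinaryGraph(
        adjacency=adj,
        sparsity=meta["sparsity"],
        source_threshold=np.nan if thr is None else thr,
        connected=meta.get("connected"),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Persist a synthetic cohort: recordings, node tables and manifest."""
    out_dir = Path(out_dir)
    (out_dir / "recordings").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for rid in manifest["recording_id"]:
        rel = f"recordings/{rid}.tsv"
        write_timeseries(cohort.recordings[rid], out_dir / rel)
        paths.append(rel)
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    for modality, table in cohort.node_tables.items():
        table.to_csv(out_dir / f"nodes_{modality}.tsv", sep="\t", index=False)
    (out_dir / "cohort_spec.json").write_text(
        json.dumps(
            {k: v if not isinstance(v, tuple) else list(v)
             for k, v in vars(cohort.spec).items()},
            indent=1,
        )
    )
    return out_dir


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t", keep_default_na=False)
    recordings = {
        row.recording_id: read_timeseries(in_dir / row.path)
        for row in manifest.itertuples()
    }
    node_tables = {}
    for modality in sorted(manifest["modality"].unique()):
        p = in_dir / f"nodes_{modality}.tsv"
        if p.exists():
            node_tables[modality] = pd.read_csv(p, sep="\t")
    spec_path = in_dir / "cohort_spec.json"
    if spec_path.exists():
        raw = json.loads(spec_path.read_text())
        raw["modalities"] = tuple(raw.get("modalities", ("eeg", "fmri")))
        spec = SyntheticCohortSpec(**raw)
    else:
        spec = SyntheticCohortSpec()
    return Cohort(
        spec=spec,
        manifest=manifest.drop(columns=["path"]),
        recordings=recordings,
        node_tables=node_tables,
    )


def read_nifti_voxels(
    path: str | Path, tr_s: float | None = None
) -> tuple[TimeSeriesMatrix, "np.ndarray"]:
    """Read a 4-D NIfTI volume as voxel time series plus mm coordinates.

    Returns (voxels × time recording, voxel centre coordinates in world/MNI
    millimetres via the image affine) — the inputs
    :func:`mmgraph.preprocess.extract_roi_timeseries` expects.  Requires
    the optional ``nibabel`` dependency.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading NIfTI requires the optional 'nibabel' "
                          "package") from exc
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    nx, ny, nz, nt = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    coords = (vox @ img.affine.T)[:, :3]
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3]) or 1.0
    ts = TimeSeriesMatrix(
        values=data.reshape(-1, nt).astype(float),
        sampling_rate=1.0 / tr_s,
        modality="fmri",
    )
    return ts, coords


def read_edf(path: str | Path, modality: str = "eeg") -> TimeSeriesMatrix:
    """Read an EDF recording into a TimeSeriesMatrix (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return TimeSeriesMatrix(
        values=raw.get_data() * 1e6,  # volts -> microvolts
        sampling_rate=float(raw.info["sfreq"]),
        modality=modality,
        node_labels=list(raw.ch_names),
    )
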