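"""Cross-modal fusion: across-subject correlation of node clustering
between EEG electrodes and fMRI ROIs, and display-file export.

For each (electrode, ROI) pair the per-subject node values (by default the
R2 - R1 change in normalized node clustering) are correlated across
subjects with Pearson r; p comes from the exact t transform with
df = n - 2.  A pair is reported significant when |r| exceeds ``r_min``
(default 0.4) *and* p <= alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossModalResult",
    "crossmodal_correlation",
    "restrict_to_significant_nodes",
    "export_brainnet_nodes",
    "read_brainnet_nodes",
]


@dataclass
class CrossModalResult:
    """Electrode × ROI correlation matrices and the filtered pair list."""

    r_matrix: pd.DataFrame  # electrodes (rows) × ROIs (columns)
    p_matrix: pd.DataFrame
    n_matrix: pd.DataFrame  # subjects used per pair (pairwise-complete)
    significant_pairs: pd.DataFrame  # electrode, roi, r, p, n
    n_subjects: int
    r_min: float
    alpha: float


def _pearson_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan, n
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def crossmodal_correlation(
    eeg_node_values: pd.DataFrame,
    fmri_node_values: pd.DataFrame,
    r_min: float = 0.4,
    alpha: float = 0.05,
) -> CrossModalResult:
    """Across-subject Pearson correlation of EEG vs fMRI node values.

    Both inputs are subject × node DataFrames indexed by subject id, in the
    same subject order (typically per-subject R2 - R1 change scores of node
    γ).  Missing values are handled pairwise-complete, with the n used per
    pair recorded.  Needs at least 4 common subjects.
    """
    if list(eeg_node_values.index) != list(fmri_node_values.index):
        raise ValueError(
            "subject index mismatch between modalities: "
            f"{list(eeg_node_values.index)} vs {list(fmri_node_values.index)}"
        )
    n_subjects = len(eeg_node_values)
    if n_subjects < 4:
        raise ValueError("cross-modal correlation needs at least 4 subjects")
    electrodes = list(eeg_node_values.columns)
    rois = list(fmri_node_values.columns)
    r = np.full((len(electrodes), len(rois)), np.nan)
    p = np.full_like(r, np.nan)
    n_used = np.zeros(r.shape, dtype=int)
    ev = eeg_node_values.to_numpy(dtype=float)
    fv = fmri_node_values.to_numpy(dtype=float)
    rows = []
    for i, e in enumerate(electrodes):
        for j, roi in enumerate(rois):
            r[i, j], p[i, j], n_used[i, j] = _pearson_with_p(ev[:, i], fv[:, j])
            if (
                np.isfinite(r[i, j])
                and abs(r[i, j]) > r_min
                and p[i, j] <= alpha
            ):
                rows.append(
                    {
                        "electrode": e,
                        "roi": roi,
                        "r": r[i, j],
                        "p": p[i, j],
                        "n": n_used[i, j],
                    }
                )
    pairs = pd.DataFrame(rows, columns=["electrode", "roi", "r", "p", "n"])
    return CrossModalResult(
        r_matrix=pd.DataFrame(r, index=electrodes, columns=rois),
        p_matrix=pd.DataFrame(p, index=electrodes, columns=rois),
        n_matrix=pd.DataFrame(n_used, index=electrodes, columns=rois),
        significant_pairs=pairs,
        n_subjects=n_subjects,
        r_min=r_min,
        alpha=alpha,
    )


def restrict_to_significant_nodes(
    eeg_node_values: pd.DataFrame,
    fmri_node_values: pd.DataFrame,
    eeg_sig_nodes: list[str],
    fmri_sig_nodes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subset both modalities to the nodes that survived group inference.

    Mirrors the published analysis, which correlated only the regions with
    significant stimulation effects (2 electrodes × 7 ROIs).
    """
    for name, nodes, df in (
        ("eeg", eeg_sig_nodes, eeg_node_values),
        ("fmri", fmri_sig_nodes, fmri_node_values),
    ):
        if not nodes:
            raise ValueError(f"{name} significant-node list is empty")
        unknown = [x for x in nodes if x not in df.columns]
        if unknown:
            raise KeyError(f"unknown {name} node label(s): {unknown}")
    return eeg_node_values[list(eeg_sig_nodes)], fmri_node_values[list(fmri_sig_nodes)]


def export_brainnet_nodes(
    node_table: pd.DataFrame,
    values,
    out_path: str | Path,
    color: float = 1,
) -> Path:
    """Write a BrainNet Viewer ``.node`` text file.

    One line per node: ``x y z color size label`` with size set to the
    supplied value (e.g. an effect size) and color to a modality code.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(node_table):
        raise ValueError("values must align with node_table rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("node sizes must be finite")
    out_path = Path(out_path)
    lines = []
    for (_, row), v in zip(node_table.iterrows(), values):
        lines.append(
            f"{row['x_mm']:g} {row['y_mm']:g} {row['z_mm']:g} "
            f"{color:g} {v:g} {row['label']}"
        )
    out_path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return out_path


def read_brainnet_nodes(path: str | Path) -> pd.DataFrame:
    """Parse a ``.node`` file back into a table (round-trip helper)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        x, y, z, color, size, label = line.split(maxsplit=5)
        rows.append(
            {
                "label": label,
                "x_mm": float(x),
                "y_mm": float(y),
                "z_mm": float(z),
                "color": float(color),
                "size": float(size),
            }
        )
    return pd.DataFrame(rows, columns=["label", "x_mm", "y_mm", "z_mm", "color", "size"])
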