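"""Group inference on small-world metrics.

Contrasts: HC vs R1 and HC vs R2 are unpaired two-sample equal-variance
t-tests (unequal group sizes allowed); R1 vs R2 is a paired t-test over
subjects recorded in both sessions.  Families of p-values (the 35 sparsity
levels of one metric, or the node set of one modality) are corrected by
Benjamini-Hochberg FDR.  Effect sizes use the equal-n pooled form

    d = (m2 - m1) / sqrt((s1^2 + s2^2) / 2),    r = d / sqrt(d^2 + 4),

which recovers the published region-level effect sizes from printed group
means and SDs (the paired-SD form is not recoverable from summary data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "two_sample_ttest_equal_var",
    "paired_ttest",
    "fdr_bh",
    "cohens_d_pooled",
    "effect_size_r",
    "compare_metric_curves",
    "node_level_comparison",
    "format_sparsity_ranges",
]

CONTRASTS = {
    "HC_vs_R1": ("HC", "R1", False),
    "HC_vs_R2": ("HC", "R2", False),
    "R1_vs_R2": ("R1", "R2", True),
}


def two_sample_ttest_equal_var(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2, two-sided p.

    The sign convention follows mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    if pooled <= 0:
        raise ValueError("zero pooled variance; t-test undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def paired_ttest(x, y) -> tuple[float, float]:
    """One-sample t-test on paired differences x - y, df = n - 1.

    Requires equal lengths with subjects aligned by the study manifest.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have identical lengths")
    if len(x) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if np.std(x - y, ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t-test undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns (rejection mask, data-dependent p threshold) where the
    threshold is the largest p-value still rejected (NaN when nothing is).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    threshold = float(p[mask].max()) if mask.any() else np.nan
    return mask, threshold


def cohens_d_pooled(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d from group summaries with equal-n pooled SD.

    d = (mean2 - mean1) / sqrt((sd1^2 + sd2^2) / 2); the sign follows the
    direction of change from group 1 to group 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (mean2 - mean1) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def effect_size_r(d: float) -> float:
    """Effect-size correlation r = d / sqrt(d^2 + 4), bounded in (-1, 1)."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    return float(d / np.sqrt(d**2 + 4.0))


def format_sparsity_ranges(sparsity: np.ndarray, mask: np.ndarray) -> str:
    """Contiguous significant sparsity runs in percent notation.

    e.g. mask over 0.11..0.45 covering 0.11-0.17 and 0.20 renders as
    "11%-17%, 20%".
    """
    sparsity = np.asarray(sparsity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    runs = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            lo = f"{round(sparsity[i] * 100):d}%"
            hi = f"{round(sparsity[j] * 100):d}%"
            runs.append(lo if i == j else f"{lo}–{hi}")
            i = j + 1
        else:
            i += 1
    return ", ".join(runs)


@dataclass
class GroupComparison:
    """Per-unit group comparison table plus family-level FDR summary.

    ``table`` has one row per unit (sparsity level or node label) with
    columns: contrast, unit, mean/sd per group, t_stat, p_value,
    fdr_significant, cohens_d, effect_r.
    """

    contrast: str
    metric: str
    table: pd.DataFrame
    q: float
    p_threshold: float
    significant_ranges: str = ""
    extra: dict = field(default_factory=dict)


def _group_arrays(
    curves_by_group: dict, metric: str, contrast: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    g1, g2, paired = CONTRASTS[contrast]
    for g in (g1, g2):
        if g not in curves_by_group or len(curves_by_group[g]) < 2:
            raise ValueError(f"contrast {contrast} needs >= 2 recordings in {g}")
    c1, c2 = curves_by_group[g1], curves_by_group[g2]
    grids = {tuple(np.round(c.sparsity, 6)) for c in c1 + c2}
    if len(grids) != 1:
        raise ValueError("all subjects must share the same sparsity grid")
    if paired:
        s1 = [c.subject_id for c in c1]
        s2 = [c.subject_id for c in c2]
        if s1 != s2:
            raise ValueError(
                "paired contrast requires identically ordered subjects; "
                f"got {s1} vs {s2}"
            )
    x1 = np.array([c.values(metric) for c in c1])  # subjects × levels
    x2 = np.array([c.values(metric) for c in c2])
    return x1, x2, np.asarray(c1[0].sparsity), paired


def compare_metric_curves(
    curves_by_group: dict,
    metric: str,
    contrast: str,
    q: float = 0.05,
) -> GroupComparison:
    """Per-sparsity group test of one metric with FDR across the grid.

    ``curves_by_group`` maps group name to a list of SmallWorldCurve; the
    paired contrast requires the R1 and R2 lists aligned subject-by-subject.
    One t-test per sparsity level; BH-FDR across all levels of this metric
    and contrast; contiguous significant ranges are reported in percent
    notation.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    x1, x2, sparsity, paired = _group_arrays(curves_by_group, metric, contrast)
    test = paired_ttest if paired else two_sample_ttest_equal_var
    t_stats = np.full(len(sparsity), np.nan)
    p_vals = np.full(len(sparsity), np.nan)
    usable = np.zeros(len(sparsity), dtype=bool)
    for li in range(len(sparsity)):
        try:
            t_stats[li], p_vals[li] = test(x1[:, li], x2[:, li])
            usable[li] = True
        except ValueError:
            # degenerate level (e.g. lambda identically 1 when every graph
            # and null reaches diameter 2): untestable, excluded from FDR
            pass
    mask = np.zeros(len(sparsity), dtype=bool)
    p_thr = np.nan
    if usable.any():
        sub_mask, p_thr = fdr_bh(p_vals[usable], q)
        mask[usable] = sub_mask
    m1, s1 = x1.mean(axis=0), x1.std(axis=0, ddof=1)
    m2, s2 = x2.mean(axis=0), x2.std(axis=0, ddof=1)
    d = (m2 - m1) / np.sqrt((s1**2 + s2**2) / 2.0)
    table = pd.DataFrame(
        {
            "contrast": contrast,
            "unit": [f"S={s:.2f}" for s in sparsity],
            "sparsity": sparsity,
            "mean_1": m1,
            "sd_1": s1,
            "mean_2": m2,
            "sd_2": s2,
            "t_stat": t_stats,
            "p_value": p_vals,
            "fdr_significant": mask,
            "cohens_d": d,
            "effect_r": d / np.sqrt(d**2 + 4.0),
        }
    )
    return GroupComparison(
        contrast=contrast,
        metric=metric,
        table=table,
        q=q,
        p_threshold=p_thr,
        significant_ranges=format_sparsity_ranges(sparsity, mask),
    )


def node_level_comparison(
    node_values_by_group: dict,
    contrast: str,
    node_labels: list[str],
    node_table: pd.DataFrame | None = None,
    q: float = 0.05,
    metric: str = "node_gamma",
) -> GroupComparison:
    """Region-level comparison of per-subject node values (e.g. node γ).

    ``node_values_by_group`` maps group name to an (n_subjects × n_nodes)
    array; the paired contrast assumes row-aligned subjects.  One test per
    node, BH-FDR across the modality's node family, effect sizes from the
    group summaries.  The table is sorted by p-value; joining ``node_table``
    (label/x_mm/y_mm/z_mm/network) attaches coordinates for display export.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    g1, g2, paired = CONTRASTS[contrast]
    x1 = np.asarray(node_values_by_group[g1], dtype=float)
    x2 = np.asarray(node_values_by_group[g2], dtype=float)
    if x1.shape[1] != len(node_labels) or x2.shape[1] != len(node_labels):
        raise ValueError("node axis must match node_labels")
    n_nodes = len(node_labels)
    t_stats = np.full(n_nodes, np.nan)
    p_vals = np.full(n_nodes, np.nan)
    usable = np.zeros(n_nodes, dtype=bool)
    test = paired_ttest if paired else two_sample_ttest_equal_var
    for j in range(n_nodes):
        a, b = x1[:, j], x2[:, j]
        if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
            try:
                t_stats[j], p_vals[j] = test(a, b)
                usable[j] = True
            except ValueError:
                pass
    mask = np.zeros(n_nodes, dtype=bool)
    if usable.any():
        sub_mask, p_thr = fdr_bh(p_vals[usable], q)
        mask[usable] = sub_mask
    else:
        p_thr = np.nan
    m1, s1 = np.nanmean(x1, axis=0), np.nanstd(x1, axis=0, ddof=1)
    m2, s2 = np.nanmean(x2, axis=0), np.nanstd(x2, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m2 - m1) / np.sqrt((s1**2 + s2**2) / 2.0)
    table = pd.DataFrame(
        {
            "contrast": contrast,
            "region": node_labels,
            f"{g1}_{metric}_mean": m1,
            f"{g1}_{metric}_sd": s1,
            f"{g2}_{metric}_mean": m2,
            f"{g2}_{metric}_sd": s2,
            "t_stat": t_stats,
            "p_value": p_vals,
            "fdr_significant": mask,
            "cohens_d": d,
            "effect_r": d / np.sqrt(d**2 + 4.0),
        }
    )
    if node_table is not None:
        coords = node_table.set_index("label")
        for col in ("x_mm", "y_mm", "z_mm", "network"):
            if col in coords.columns:
                table.insert(
                    2 if col != "network" else len(table.columns),
                    col,
                    [coords.at[lbl, col] if lbl in coords.index else np.nan
                     for lbl in node_labels],
                )
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return GroupComparison(
        contrast=contrast,
        metric=metric,
        table=table,
        q=q,
        p_threshold=p_thr,
        extra={"n_untestable_nodes": int((~usable).sum())},
    )
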