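"""Published region-level reference data.

The shipped table lists, for each brain region with a significant
stimulation effect in the original patient study, its MNI coordinates and
the group mean ± SD of the normalized node clustering coefficient before
(R1) and after (R2) stimulation.  Effect sizes are deliberately not
stored: they are recomputed from these summaries via
:func:`mmgraph.groupstats.cohens_d_pooled` and
:func:`mmgraph.groupstats.effect_size_r`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .groupstats import cohens_d_pooled, effect_size_r

__all__ = ["load_reference_regions", "reference_effect_sizes"]


def load_reference_regions() -> pd.DataFrame:
    """Region table: modality, region, MNI mm coordinates, R1/R2 γ mean ± SD."""
    with resources.files("mmgraph.data").joinpath("reference_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_effect_sizes() -> pd.DataFrame:
    """Reference regions with Cohen's d and effect-size r recomputed from
    the printed group means and SDs."""
    df = load_reference_regions().copy()
    d = [
        cohens_d_pooled(r.r1_gamma_mean, r.r1_gamma_sd, r.r2_gamma_mean, r.r2_gamma_sd)
        for r in df.itertuples()
    ]
    df["cohens_d"] = d
    df["effect_r"] = [effect_size_r(x) for x in d]
    return df
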