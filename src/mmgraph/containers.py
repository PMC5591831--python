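"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_MODALITIES = ("eeg", "fmri")
VALID_GROUPS = ("HC", "R1", "R2")


@dataclass
class TimeSeriesMatrix:
    """One recording: a node × sample real matrix with acquisition metadata.

    ``sampling_rate`` is in Hz for EEG and 1/TR (TR in seconds) for fMRI;
    EEG values are in microvolts, fMRI in arbitrary BOLD units.
    """

    values: np.ndarray
    sampling_rate: float
    modality: str
    subject_id: str = ""
    group: str | None = None
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node × sample matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"modality must be one of {VALID_MODALITIES}")
        if self.group is not None and self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}")
        if not self.node_labels:
            width = len(str(self.values.shape[0]))
            self.node_labels = [
                f"n{i + 1:0{width}d}" for i in range(self.values.shape[0])
            ]
        if len(self.node_labels) != self.values.shape[0]:
            raise ValueError("node_labels length must match the node count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        """Copy of this recording with the signal replaced, metadata kept."""
        return replace(self, values=np.asarray(values, dtype=float))


def as_node_labels(labels: Sequence[str] | None, n: int) -> list[str]:
    if labels is None:
        width = len(str(n))
        return [f"n{i + 1:0{width}d}" for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} node labels, got {len(labels)}")
    return labels
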