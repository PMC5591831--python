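"""Signal preprocessing: EEG band decomposition and epoch rejection,
fMRI nuisance regression, temporal filtering and sphere-ROI extraction.

Filtering is zero-phase throughout (forward-backward 4th-order Butterworth),
so epoch boundaries stay aligned between modalities.  Amplitude-based epoch
rejection replaces the visual/ICA artifact screening a human operator would
perform on real recordings; it is the deterministic part of that procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.distance import cdist

from .containers import TimeSeriesMatrix

__all__ = [
    "BandDefinition",
    "EpochReport",
    "DEFAULT_BANDS",
    "drop_initial_dynamics",
    "bandpass_filter",
    "split_bands",
    "epoch_and_reject",
    "regress_nuisance",
    "extract_roi_timeseries",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band (edges in Hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, "
                f"got ({self.low_hz}, {self.high_hz})"
            )


#: The four analysis bands: theta, alpha and the split beta range.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 20.0, 30.0),
)


@dataclass(frozen=True)
class EpochReport:
    """Bookkeeping of amplitude-based epoch rejection."""

    epoch_length_s: float
    n_total: int
    n_rejected: int
    n_kept: int
    rejected_indices: tuple[int, ...]
    threshold_uv: float

    def __post_init__(self) -> None:
        if self.n_kept + self.n_rejected != self.n_total:
            raise ValueError("epoch accounting violated: kept + rejected != total")


def drop_initial_dynamics(
    ts: TimeSeriesMatrix, n_dynamics: int, tr_s: float
) -> TimeSeriesMatrix:
    """Remove the leading ``n_dynamics`` scanner volumes' worth of signal.

    Discards the scanner start-up transition (signal inhomogeneity during
    the first dynamics) from either modality: ``n_dynamics * tr_s`` seconds
    are cut from the front of every channel.
    """
    if n_dynamics < 0:
        raise ValueError("n_dynamics must be nonnegative")
    if n_dynamics == 0:
        return ts.with_values(ts.values.copy())
    n_drop = int(round(n_dynamics * tr_s * ts.sampling_rate))
    if n_drop >= ts.n_samples:
        raise ValueError(
            f"recording of {ts.n_samples} samples too short to drop "
            f"{n_dynamics} dynamics ({n_drop} samples)"
        )
    return ts.with_values(ts.values[:, n_drop:])


def _bandpass_sos(low_hz: float, high_hz: float, fs: float):
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band edges ({low_hz}, {high_hz}) Hz for sampling rate "
            f"{fs} Hz (Nyquist {nyq} Hz)"
        )
    return butter(4, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def bandpass_filter(
    ts: TimeSeriesMatrix, low_hz: float, high_hz: float
) -> TimeSeriesMatrix:
    """Zero-phase band-pass (forward-backward 4th-order Butterworth).

    Forward-backward application squares the magnitude response and cancels
    the group delay, so filtered epochs remain aligned with the original
    samples.
    """
    sos = _bandpass_sos(low_hz, high_hz, ts.sampling_rate)
    return ts.with_values(sosfiltfilt(sos, ts.values, axis=1))


def split_bands(
    ts: TimeSeriesMatrix,
    bands: tuple[BandDefinition, ...] | list[BandDefinition] = DEFAULT_BANDS,
) -> dict[str, TimeSeriesMatrix]:
    """One band-limited copy of the recording per band definition."""
    return {b.name: bandpass_filter(ts, b.low_hz, b.high_hz) for b in bands}


def epoch_and_reject(
    ts: TimeSeriesMatrix,
    epoch_length_s: float = 3.0,
    threshold_uv: float = 150.0,
    *,
    criterion: str = "peak_to_peak",
) -> tuple[TimeSeriesMatrix, EpochReport]:
    """Cut into fixed-length epochs, drop high-amplitude ones, reconcatenate.

    An epoch is rejected when any channel's amplitude within it exceeds
    ``threshold_uv`` microvolts, with "amplitude" read as peak-to-peak range
    by default (``criterion="abs"`` switches to the absolute-value rule).
    A trailing partial epoch is dropped; survivors are concatenated in time
    order.  Rejecting every epoch is an error, since the downstream
    correlation would be undefined.
    """
    if criterion not in ("peak_to_peak", "abs"):
        raise ValueError("criterion must be 'peak_to_peak' or 'abs'")
    n_per = epoch_length_s * ts.sampling_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch length {epoch_length_s}s is not a whole number of samples "
            f"at {ts.sampling_rate} Hz"
        )
    n_per = int(round(n_per))
    n_total = ts.n_samples // n_per
    if n_total == 0:
        raise ValueError("recording shorter than one epoch")
    x = ts.values[:, : n_total * n_per]
    epochs = x.reshape(ts.n_nodes, n_total, n_per)
    if criterion == "peak_to_peak":
        amp = epochs.max(axis=2) - epochs.min(axis=2)
    else:
        amp = np.abs(epochs).max(axis=2)
    bad = (amp > threshold_uv).any(axis=0)
    rejected = tuple(int(i) for i in np.flatnonzero(bad))
    kept = np.flatnonzero(~bad)
    if kept.size == 0:
        raise ValueError(
            f"all {n_total} epochs exceeded {threshold_uv} uV; "
            "no data left for connectivity"
        )
    out = epochs[:, kept, :].reshape(ts.n_nodes, kept.size * n_per)
    report = EpochReport(
        epoch_length_s=epoch_length_s,
        n_total=n_total,
        n_rejected=len(rejected),
        n_kept=int(kept.size),
        rejected_indices=rejected,
        threshold_uv=threshold_uv,
    )
    return ts.with_values(out), report


def regress_nuisance(
    ts: TimeSeriesMatrix, confound_matrix: np.ndarray | None
) -> TimeSeriesMatrix:
    """Residualize every channel on [intercept + confounds] by least squares.

    Used to remove white-matter / CSF signals from fMRI channels.  The
    residuals are exactly orthogonal to each (demeaned) confound column.
    An empty confound set reduces to demeaning.
    """
    n = ts.n_samples
    if confound_matrix is None or np.size(confound_matrix) == 0:
        design = np.ones((n, 1))
    else:
        conf = np.atleast_2d(np.asarray(confound_matrix, dtype=float))
        if conf.shape[0] != n:
            if conf.shape[1] == n:
                conf = conf.T
            else:
                raise ValueError(
                    f"confound rows ({conf.shape[0]}) must match the sample "
                    f"count ({n})"
                )
        design = np.column_stack([np.ones(n), conf])
        demeaned = conf - conf.mean(axis=0)
        if np.linalg.matrix_rank(demeaned) < conf.shape[1]:
            raise ValueError(
                "confound matrix is rank-deficient after demeaning; "
                "remove collinear or constant confound columns"
            )
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    resid = ts.values.T - design @ beta
    return ts.with_values(resid.T)


def extract_roi_timeseries(
    voxel_grid_ts: TimeSeriesMatrix,
    voxel_coords_mm: np.ndarray,
    roi_table,
    radius_mm: float = 5.0,
) -> tuple[TimeSeriesMatrix, list[str]]:
    """Average voxel signals within spherical ROIs.

    Each ROI signal is the unweighted mean over voxels whose centre lies
    within ``radius_mm`` (Euclidean, MNI millimetres) of the ROI centre.
    Returns the ROI-level recording and the labels of any ROIs that
    captured zero voxels; those rows are zero-filled, flagged in the
    returned list, and a warning is issued (never silently dropped).
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    coords = np.asarray(voxel_coords_mm, dtype=float)
    if coords.shape != (voxel_grid_ts.n_nodes, 3):
        raise ValueError("voxel_coords_mm must be (n_voxels, 3) matching the grid")
    centers = np.asarray(roi_table[["x_mm", "y_mm", "z_mm"]], dtype=float)
    labels = list(roi_table["label"])
    dist = cdist(centers, coords)
    out = np.full((len(labels), voxel_grid_ts.n_samples), np.nan)
    empty: list[str] = []
    for i, label in enumerate(labels):
        members = dist[i] <= radius_mm
        if not members.any():
            empty.append(label)
            continue
        out[i] = voxel_grid_ts.values[members].mean(axis=0)
    if empty:
        warnings.warn(
            f"{len(empty)} ROI(s) captured zero voxels at radius "
            f"{radius_mm} mm: {empty[:5]}{'...' if len(empty) > 5 else ''}",
            stacklevel=2,
        )
    ts = TimeSeriesMatrix(
        values=np.where(np.isnan(out), 0.0, out),
        sampling_rate=voxel_grid_ts.sampling_rate,
        modality=voxel_grid_ts.modality,
        subject_id=voxel_grid_ts.subject_id,
        group=voxel_grid_ts.group,
        node_labels=labels,
    )
    return ts, empty
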