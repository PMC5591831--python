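"""Filtering, epoching/rejection, nuisance regression, ROI extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmgraph.containers import TimeSeriesMatrix
from mmgraph.preprocess import (
    DEFAULT_BANDS,
    BandDefinition,
    bandpass_filter,
    drop_initial_dynamics,
    epoch_and_reject,
    extract_roi_timeseries,
    regress_nuisance,
    split_bands,
)


def _ts(values, rate=250.0, modality="eeg"):
    return TimeSeriesMatrix(values=values, sampling_rate=rate, modality=modality)


def _sine(freq, rate, dur_s, n_ch=2):
    t = np.arange(int(dur_s * rate)) / rate
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


class TestDropInitialDynamics:
    def test_recorded_protocol_lengths(self):
        # 185 volumes recorded, first 5 excluded -> 180 analyzed
        ts = _ts(np.random.default_rng(0).normal(size=(4, 185)),
                 rate=1 / 3.0, modality="fmri")
        out = drop_initial_dynamics(ts, 5, tr_s=3.0)
        assert out.n_samples == 180

    def test_zero_dynamics_is_identity(self, eeg_ts):
        out = drop_initial_dynamics(eeg_ts, 0, tr_s=3.0)
        assert np.array_equal(out.values, eeg_ts.values)

    def test_eeg_sample_count(self):
        ts = _ts(np.zeros((2, 10000)), rate=250.0)
        out = drop_initial_dynamics(ts, 5, tr_s=3.0)
        assert ts.n_samples - out.n_samples == 5 * 3 * 250

    def test_too_short_recording_fails(self):
        ts = _ts(np.zeros((2, 100)), rate=250.0)
        with pytest.raises(ValueError, match="too short"):
            drop_initial_dynamics(ts, 5, tr_s=3.0)


class TestBandpass:
    def test_passband_tone_preserved(self):
        ts = _ts(_sine(10.0, 250.0, 60.0))
        out = bandpass_filter(ts, 8.0, 13.0)
        ratio = np.sqrt((out.values**2).mean() / (ts.values**2).mean())
        assert ratio >= 0.95

    def test_stopband_tone_suppressed(self):
        ts = _ts(_sine(10.0, 250.0, 60.0))
        out = bandpass_filter(ts, 4.0, 8.0)
        ratio = np.sqrt((out.values**2).mean() / (ts.values**2).mean())
        assert ratio <= 0.1

    def test_zero_in_zero_out(self):
        out = bandpass_filter(_ts(np.zeros((3, 1000))), 8.0, 13.0)
        assert np.allclose(out.values, 0.0)

    def test_zero_phase_symmetric_pulse_stays_symmetric(self):
        n = 4001
        x = np.zeros((1, n))
        center = n // 2
        t = np.arange(n) - center
        x[0] = np.exp(-(t / 40.0) ** 2) * np.cos(2 * np.pi * 10 * t / 250.0)
        out = bandpass_filter(_ts(x), 8.0, 13.0).values[0]
        assert np.allclose(out, out[::-1], atol=1e-8)

    def test_invalid_edges_rejected(self, eeg_ts):
        with pytest.raises(ValueError, match="band edges"):
            bandpass_filter(eeg_ts, 30.0, 20.0)
        with pytest.raises(ValueError, match="band edges"):
            bandpass_filter(eeg_ts, 20.0, 200.0)  # above Nyquist


class TestSplitBands:
    def test_default_band_names_and_edges(self):
        assert [b.name for b in DEFAULT_BANDS] == ["theta", "alpha", "beta1", "beta2"]
        assert [(b.low_hz, b.high_hz) for b in DEFAULT_BANDS] == [
            (4.0, 8.0), (8.0, 13.0), (13.0, 20.0), (20.0, 30.0)
        ]

    def test_mixed_tones_separate_into_their_bands(self):
        x = _sine(6.0, 250.0, 60.0) + _sine(25.0, 250.0, 60.0)
        out = split_bands(_ts(x))
        assert set(out) == {"theta", "alpha", "beta1", "beta2"}
        power = {name: (b.values**2).mean() for name, b in out.items()}
        assert power["theta"] > 10 * power["alpha"]
        assert power["beta2"] > 10 * power["beta1"]

    def test_empty_band_list(self, eeg_ts):
        assert split_bands(eeg_ts, []) == {}

    def test_invalid_band_definition(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 8.0, 4.0)


class TestEpochReject:
    def test_protocol_epoch_count(self):
        # 540 s at 250 Hz in 3-s epochs -> 180 epochs
        ts = _ts(np.random.default_rng(1).normal(size=(4, 135000)))
        out, report = epoch_and_reject(ts, 3.0, 150.0)
        assert report.n_total == 180
        assert report.n_rejected == 0
        assert out.n_samples == 135000

    def test_large_step_on_one_channel_rejects_epoch(self):
        ts_arr = np.zeros((3, 10 * 750))
        ts_arr[1, 4 * 750 + 100:4 * 750 + 200] = 200.0  # 200 uV step in epoch 4
        out, report = epoch_and_reject(_ts(ts_arr), 3.0, 150.0)
        assert report.rejected_indices == (4,)
        assert report.n_kept == 9
        assert out.n_samples == 9 * 750

    def test_all_zero_recording_keeps_everything(self):
        ts = _ts(np.zeros((2, 2000)))
        out, report = epoch_and_reject(_ts(np.zeros((2, 2000))), 3.0, 150.0)
        assert report.n_rejected == 0
        assert out.n_samples == (2000 // 750) * 750  # partial epoch dropped

    def test_all_epochs_rejected_is_an_error(self):
        ts = _ts(np.random.default_rng(0).normal(scale=500.0, size=(2, 3000)))
        with pytest.raises(ValueError, match="all .* epochs"):
            epoch_and_reject(ts, 3.0, 150.0)

    def test_absolute_value_criterion_option(self):
        # constant 100 uV offset: peak-to-peak 0 (kept), absolute 100 (rejected)
        ts_arr = np.zeros((1, 2 * 750))
        ts_arr[0, :750] = 100.0
        _, rep_ptp = epoch_and_reject(_ts(ts_arr), 3.0, 80.0)
        assert rep_ptp.n_rejected == 0
        _, rep_abs = epoch_and_reject(_ts(ts_arr), 3.0, 80.0, criterion="abs")
        assert rep_abs.rejected_indices == (0,)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_epoch_accounting_identity(self, seed):
        rng = np.random.default_rng(seed)
        ts = _ts(rng.normal(scale=60.0, size=(3, 6000)))
        try:
            _, report = epoch_and_reject(ts, 3.0, rng.uniform(100, 400))
        except ValueError:
            return  # everything rejected: error path, accounting untestable
        assert report.n_kept + report.n_rejected == report.n_total


class TestNuisanceRegression:
    def test_channel_equal_to_confound_vanishes(self, rng):
        conf = rng.normal(size=(500, 1))
        ts = _ts(conf.T.copy(), modality="fmri", rate=1 / 3.0)
        out = regress_nuisance(ts, conf)
        assert np.abs(out.values).max() < 1e-10

    def test_empty_confounds_demeans(self, rng):
        x = rng.normal(loc=5.0, size=(3, 400))
        out = regress_nuisance(_ts(x, modality="fmri", rate=1 / 3.0), None)
        assert np.allclose(out.values, x - x.mean(axis=1, keepdims=True))

    def test_residual_orthogonal_to_confounds(self, rng):
        conf = rng.normal(size=(600, 2))
        signal = conf @ np.array([[1.5], [-0.7]]) + rng.normal(size=(600, 1))
        ts = _ts(signal.T, modality="fmri", rate=1 / 3.0)
        out = regress_nuisance(ts, conf)
        demeaned = conf - conf.mean(axis=0)
        corr = demeaned.T @ out.values.T / len(conf)
        assert np.abs(corr).max() < 1e-10

    def test_idempotent(self, rng):
        conf = rng.normal(size=(300, 2))
        ts = _ts(rng.normal(size=(4, 300)), modality="fmri", rate=1 / 3.0)
        once = regress_nuisance(ts, conf)
        twice = regress_nuisance(once, conf)
        assert np.abs(once.values - twice.values).max() < 1e-10

    def test_rank_deficient_design_fails(self, rng):
        col = rng.normal(size=(300, 1))
        conf = np.hstack([col, 2 * col])
        ts = _ts(rng.normal(size=(2, 300)), modality="fmri", rate=1 / 3.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            regress_nuisance(ts, conf)


class TestRoiExtraction:
    def _grid(self, rng, n_vox=27):
        coords = np.array(
            [[x, y, z] for x in (0, 4, 8) for y in (0, 4, 8) for z in (0, 4, 8)],
            dtype=float,
        )
        ts = _ts(rng.normal(size=(len(coords), 50)), modality="fmri", rate=1 / 3.0)
        return ts, coords

    def test_sphere_mean_of_two_voxels(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [30.0, 0, 0]])
        vals = np.array([[1.0, 5.0], [3.0, 7.0], [9.0, 9.0]])
        ts = _ts(vals, modality="fmri", rate=1 / 3.0)
        roi = pd.DataFrame(
            {"label": ["A"], "x_mm": [1.5], "y_mm": [0.0], "z_mm": [0.0]}
        )
        out, empty = extract_roi_timeseries(ts, coords, roi, radius_mm=5.0)
        assert not empty
        assert np.allclose(out.values[0], [2.0, 6.0])

    def test_single_voxel_roi_copies_series(self, rng):
        ts, coords = self._grid(rng)
        roi = pd.DataFrame(
            {"label": ["B"], "x_mm": [4.0], "y_mm": [4.0], "z_mm": [4.0]}
        )
        out, _ = extract_roi_timeseries(ts, coords, roi, radius_mm=2.0)
        center_idx = np.flatnonzero((coords == [4, 4, 4]).all(axis=1))[0]
        assert np.array_equal(out.values[0], ts.values[center_idx])

    def test_empty_roi_flagged_with_warning(self, rng):
        ts, coords = self._grid(rng)
        roi = pd.DataFrame(
            {"label": ["far"], "x_mm": [500.0], "y_mm": [0.0], "z_mm": [0.0]}
        )
        with pytest.warns(UserWarning, match="zero voxels"):
            out, empty = extract_roi_timeseries(ts, coords, roi, radius_mm=5.0)
        assert empty == ["far"]

    def test_permutation_invariant_to_voxel_order(self, rng):
        ts, coords = self._grid(rng)
        roi = pd.DataFrame(
            {"label": ["C"], "x_mm": [2.0], "y_mm": [2.0], "z_mm": [2.0]}
        )
        out1, _ = extract_roi_timeseries(ts, coords, roi, radius_mm=5.0)
        perm = rng.permutation(len(coords))
        ts_p = _ts(ts.values[perm], modality="fmri", rate=1 / 3.0)
        out2, _ = extract_roi_timeseries(ts_p, coords[perm], roi, radius_mm=5.0)
        assert np.allclose(out1.values, out2.values)
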