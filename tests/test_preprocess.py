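"""Signal-conditioning contracts: referencing, resampling, filtering, epoching."""

import numpy as np
import pytest

from vnspredict import preprocess
from vnspredict.recording import BANDS

from conftest import make_recording


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestRereference:
    def test_two_channel_mean_removal(self):
        rec = make_recording([[1.0, 1.0], [3.0, 3.0]], labels=["C3", "C4"])
        out = preprocess.rereference_average(rec)
        np.testing.assert_allclose(out.data, [[-1.0, -1.0], [1.0, 1.0]])

    def test_idempotent_on_zero_mean_input(self, rng):
        data = rng.standard_normal((4, 100))
        data -= data.mean(axis=0)
        rec = make_recording(data)
        out = preprocess.rereference_average(rec)
        np.testing.assert_allclose(out.data, data, atol=1e-14)

    def test_random_19_channel_columns_zeroed(self, rng):
        rec = make_recording(rng.standard_normal((19, 1000)))
        out = preprocess.rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            preprocess.rereference_average(make_recording(np.ones((1, 10))))


class TestResample:
    def test_noop_at_target_rate(self, rng):
        rec = make_recording(rng.standard_normal((2, 5000)), fs=500.0)
        out = preprocess.resample(rec, 500.0)
        assert out.n_samples == 5000 and out.sampling_rate == 500.0

    def test_downsample_halves_samples(self, rng):
        rec = make_recording(rng.standard_normal((2, 10000)), fs=1000.0)
        out = preprocess.resample(rec, 500.0)
        assert out.n_samples == 5000
        assert out.sampling_rate == 500.0

    def test_sinusoid_preserved(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 5 * t), fs=fs)
        out = preprocess.resample(rec, 500.0)
        t2 = np.arange(out.n_samples) / 500.0
        ref = np.sin(2 * np.pi * 5 * t2)
        r = np.corrcoef(out.data[0], ref)[0, 1]
        assert r > 0.999

    def test_invalid_rate_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError):
            preprocess.resample(rec, 0)


class TestBroadbandFilter:
    fs = 500.0

    def _tone(self, freq, seconds=10):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return make_recording(np.sin(2 * np.pi * freq * t), fs=self.fs)

    def test_50hz_attenuated(self):
        # steady-state attenuation; the boundary transient is excluded, as the
        # pipeline itself does before epoching
        rec = self._tone(50.0)
        out = preprocess.filter_broadband(rec)
        interior = slice(int(2 * self.fs), -int(2 * self.fs))
        assert _rms(out.data[0][interior]) < 0.03 * _rms(rec.data[0][interior])

    def test_10hz_passband(self):
        rec = self._tone(10.0)
        out = preprocess.filter_broadband(rec)
        assert abs(_rms(out.data) / _rms(rec.data) - 1) < 0.1

    def test_dc_removed(self):
        rec = make_recording(np.full(5000, 7.0), fs=self.fs)
        out = preprocess.filter_broadband(rec)
        assert _rms(out.data) < 0.05 * 7.0

    def test_low_sampling_rate_rejected(self):
        rec = make_recording(np.random.default_rng(0).standard_normal(1000), fs=100.0)
        with pytest.raises(ValueError, match="100 Hz"):
            preprocess.filter_broadband(rec)


class TestBandFilter:
    fs = 250.0

    def _tone(self, freq, seconds=10):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return make_recording(np.sin(2 * np.pi * freq * t), fs=self.fs)

    def test_alpha_preserves_10hz(self):
        rec = self._tone(10.0)
        out = preprocess.filter_band(rec, BANDS["alpha"])
        assert abs(_rms(out.data) / _rms(rec.data) - 1) < 0.1

    def test_theta_attenuates_10hz(self):
        rec = self._tone(10.0)
        out = preprocess.filter_band(rec, BANDS["theta"])
        assert _rms(out.data) < 0.1 * _rms(rec.data)

    def test_theta_isolates_6hz_component(self):
        t = np.arange(int(10 * self.fs)) / self.fs
        six = np.sin(2 * np.pi * 6 * t)
        rec = make_recording(six + np.sin(2 * np.pi * 10 * t), fs=self.fs)
        out = preprocess.filter_band(rec, BANDS["theta"])
        interior = slice(int(2 * self.fs), int(8 * self.fs))
        r = np.corrcoef(out.data[0][interior], six[interior])[0, 1]
        assert r > 0.99

    def test_band_above_nyquist_rejected(self):
        rec = self._tone(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess.filter_band(rec, BANDS["high_beta"].__class__("bad", 30.0, 200.0))


class TestEpoching:
    def test_six_minutes_at_500hz(self):
        rec = make_recording(np.zeros(180000) + np.arange(180000), fs=500.0)
        ep = preprocess.segment_epochs(rec, 2.0)
        assert ep.n_epochs == 180
        assert ep.epochs.shape == (180, 1, 1000)

    def test_trailing_partial_dropped(self):
        rec = make_recording(np.arange(5 * 250, dtype=float), fs=250.0)
        ep = preprocess.segment_epochs(rec, 2.0)
        assert ep.n_epochs == 2

    def test_partition_property(self, rng):
        data = rng.standard_normal((3, 1250))
        rec = make_recording(data, fs=250.0)
        ep = preprocess.segment_epochs(rec, 2.0)
        recon = np.concatenate([e for e in ep.epochs], axis=1)
        np.testing.assert_array_equal(recon, data[:, :1000])

    def test_too_short_rejected(self):
        rec = make_recording(np.zeros(100), fs=250.0)
        with pytest.raises(ValueError, match="shorter than epoch"):
            preprocess.segment_epochs(rec, 2.0)

    def test_edge_trim(self, rng):
        data = rng.standard_normal((2, 2500))
        rec = make_recording(data, fs=250.0)
        ep = preprocess.segment_epochs(rec, 2.0, edge_trim=1.0)
        assert ep.n_epochs == 4  # 10 s - 2 s trim -> 8 s
        np.testing.assert_array_equal(ep.epochs[0], data[:, 250:750])


class TestAmplitudeRejection:
    def test_high_amplitude_epochs_dropped(self, rng):
        data = rng.standard_normal((2, 2000))
        data[0, 600] = 100.0  # artifact in the second epoch
        ep = preprocess.segment_epochs(make_recording(data, fs=250.0), 2.0)
        kept = preprocess.reject_high_amplitude(ep, ptp_threshold=50.0)
        assert kept.n_epochs == ep.n_epochs - 1


def test_filters_are_zero_phase():
    """A symmetric pulse must stay symmetric through every filter."""
    fs = 500.0
    n = 10000
    x = np.zeros(n)
    center = n // 2
    width = 100
    x[center - width: center + width + 1] = np.hanning(2 * width + 1)
    rec = make_recording(x, fs=fs)
    for out in (
        preprocess.filter_broadband(rec),
        preprocess.filter_band(rec, BANDS["alpha"]),
    ):
        y = out.data[0]
        left = y[center - 2000: center][::-1]
        right = y[center + 1: center + 2001]
        assert np.abs(left - right).max() < 1e-6 * np.abs(y).max()
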