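"""Preprocessing chain: filtering, resampling, segmentation, interpolation,
rejection, re-referencing, cropping, averaging."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import make_epoch
from fpvs.montage import Montage
from fpvs.paradigm import DesignSpec, build_sequence
from fpvs.preprocess import (Epoch, PreprocessConfig, average_repetitions,
                             bandpass_filter, crop_stimulation,
                             interpolate_channels, preprocess_recording,
                             reject_repetitions, rereference_average, resample,
                             segment_sequences, _bandpass_sos)
from fpvs.simulate import NoiseSpec, Recording, ResponseSpec, simulate_recording


def _sine_recording(freq_hz, fs_hz=512.0, dur_s=44.0, n_channels=2, amp=1.0):
    t = np.arange(int(dur_s * fs_hz)) / fs_hz
    data = np.tile(amp * np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    return Recording(data=data, fs_hz=fs_hz, montage=None,
                     events=[(0.0, dur_s, "sequence/test")])


def _interior_amplitude(rec, freq_hz):
    """Peak FFT amplitude at freq over the central 40 s (away from filter edges)."""
    i0 = int(2.0 * rec.fs_hz)
    n = int(40.0 * rec.fs_hz)
    seg = rec.data[0, i0:i0 + n]
    amps = np.abs(np.fft.rfft(seg)) * 2 / n
    k = int(round(freq_hz * n / rec.fs_hz))
    return amps[k]


class TestBandpass:
    def test_6hz_amplitude_preserved_within_1pct(self):
        rec = bandpass_filter(_sine_recording(6.0), PreprocessConfig())
        assert _interior_amplitude(rec, 6.0) == pytest.approx(1.0, rel=0.01)

    def test_dc_attenuated(self):
        rec = _sine_recording(6.0)
        rec.data = np.ones_like(rec.data)
        out = bandpass_filter(rec, PreprocessConfig())
        assert np.abs(out.data[:, 1024:-1024]).max() < 0.05

    def test_slow_drift_attenuated_by_20db(self):
        """Forward-backward 4th-order Butterworth response at 0.01 Hz."""
        cfg = PreprocessConfig()
        sos = _bandpass_sos(cfg, 512.0)
        _, h = sps.sosfreqz(sos, worN=[0.01], fs=512.0)
        assert 40 * np.log10(np.abs(h[0])) < -20  # doubled: two passes

    def test_cutoff_above_nyquist_rejected(self):
        rec = _sine_recording(6.0, fs_hz=128.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, PreprocessConfig(bandpass_hi_hz=100.0))


class TestResample:
    def test_2048_to_512_quarters_samples(self):
        rec = _sine_recording(6.0, fs_hz=2048.0)
        assert rec.n_samples == 90112
        out = resample(rec, PreprocessConfig())
        assert out.n_samples == 22528 and out.fs_hz == 512.0

    def test_6hz_amplitude_preserved_within_1pct(self):
        out = resample(_sine_recording(6.0, fs_hz=2048.0), PreprocessConfig())
        assert _interior_amplitude(out, 6.0) == pytest.approx(1.0, rel=0.01)

    def test_no_content_above_new_nyquist(self):
        rng = np.random.default_rng(0)
        rec = _sine_recording(6.0, fs_hz=2048.0)
        rec.data = rng.standard_normal(rec.data.shape)
        out = resample(rec, PreprocessConfig())
        # content above 256 Hz cannot be represented at 512 Hz by construction
        assert out.fs_hz / 2 == 256.0

    def test_upsampling_rejected(self):
        rec = _sine_recording(6.0, fs_hz=256.0)
        with pytest.raises(ValueError):
            resample(rec, PreprocessConfig(resample_to_hz=512.0))


class TestSegmentation:
    def test_one_epoch_per_marker(self):
        fs = 512.0
        data = np.zeros((3, int(4 * 44 * fs)))
        events = [(44.0 * i, 44.0, f"sequence/{i}") for i in range(4)]
        rec = Recording(data=data, fs_hz=fs, montage=None, events=events)
        epochs = segment_sequences(rec)
        assert len(epochs) == 4
        assert all(ep.n_samples == 22528 for ep in epochs)

    def test_marker_too_close_to_eof_dropped(self, caplog):
        fs = 512.0
        rec = Recording(data=np.zeros((2, int(60 * fs))), fs_hz=fs, montage=None,
                        events=[(0.0, 44.0, "sequence/a"), (30.0, 44.0, "sequence/b")])
        with caplog.at_level("WARNING"):
            epochs = segment_sequences(rec)
        assert len(epochs) == 1
        assert any("dropped" in m for m in caplog.messages)

    def test_no_markers_is_error(self):
        rec = Recording(data=np.zeros((2, 512)), fs_hz=512.0, montage=None, events=[])
        with pytest.raises(ValueError, match="marker"):
            segment_sequences(rec)


class TestInterpolation:
    @pytest.fixture()
    def toy_montage(self):
        # target at the pole; a, b, c strictly nearest, d and e far away
        theta = np.array([0.10, 0.14, 0.18, 0.8, 1.0])
        phi = np.array([0.0, 1.5, 3.0, 4.0, 5.0])
        pos = np.c_[np.cos(phi) * np.sin(theta), np.sin(phi) * np.sin(theta),
                    np.cos(theta)]
        pos = np.vstack([[0.0, 0.0, 1.0], pos])
        return Montage(labels=["target", "a", "b", "c", "d", "e"], positions=pos)

    def test_mean_of_three_nearest_constant_neighbors(self, toy_montage):
        data = np.zeros((6, 100))
        for i, v in enumerate([99.0, 1.0, 2.0, 3.0, 4.0, 5.0]):
            data[i] = v
        # nearest three good channels carry 1, 2, 3 -> interpolated = 2
        ep = make_epoch(data, montage=toy_montage)
        out = interpolate_channels(ep, ["target"], toy_montage)
        np.testing.assert_allclose(out.data[0], 2.0)
        np.testing.assert_array_equal(out.data[1:], data[1:])
        assert out.interpolated == ["target"]

    def test_empty_bad_list_is_identity(self, toy_montage):
        ep = make_epoch(np.random.default_rng(0).normal(size=(6, 50)),
                        montage=toy_montage)
        out = interpolate_channels(ep, [], toy_montage)
        np.testing.assert_array_equal(out.data, ep.data)

    def test_bad_channels_never_used_as_neighbors(self, toy_montage):
        data = np.zeros((6, 10))
        data[0] = 100.0  # target, bad
        data[1] = 100.0  # a, also bad
        data[2:] = 7.0
        ep = make_epoch(data, montage=toy_montage)
        out = interpolate_channels(ep, ["target", "a"], toy_montage)
        np.testing.assert_allclose(out.data[0], 7.0)
        np.testing.assert_allclose(out.data[1], 7.0)

    def test_more_than_three_bad_channels_refused(self, toy_montage):
        ep = make_epoch(np.zeros((6, 10)), montage=toy_montage)
        with pytest.raises(ValueError, match="reject"):
            interpolate_channels(ep, ["a", "b", "c", "d"], toy_montage)


class TestRejection:
    def _epochs(self, peak_uv):
        rng = np.random.default_rng(1)
        out = []
        for i, p in enumerate(peak_uv):
            data = rng.normal(scale=1.0, size=(4, 1000))
            data[0, 500] = p
            out.append(make_epoch(data, notation="words-digits",
                                  condition="experimental", repetition=i))
        return out

    def test_all_below_threshold_kept(self):
        kept, logd = reject_repetitions(self._epochs([10, 10, 10]))
        assert len(kept) == 3
        assert logd[("words-digits", "experimental")] == {"kept": 3, "rejected": 0}

    def test_artifact_epoch_removed(self):
        epochs = self._epochs([10, 500, 10])
        kept, logd = reject_repetitions(epochs)
        assert len(kept) == 2 and epochs[1] not in kept
        assert logd[("words-digits", "experimental")]["rejected"] == 1

    def test_infinite_threshold_is_identity(self):
        epochs = self._epochs([10, 500, 10])
        kept, _ = reject_repetitions(epochs,
                                     PreprocessConfig(rejection_threshold_uv=np.inf))
        assert kept == epochs

    def test_all_rejected_is_error(self):
        with pytest.raises(ValueError, match="rejected"):
            reject_repetitions(self._epochs([500, 600]))


class TestRereference:
    def test_per_sample_channel_mean_zero(self):
        rng = np.random.default_rng(2)
        ep = make_epoch(rng.normal(size=(8, 300)) + 5.0)
        out = rereference_average(ep)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_idempotent_and_symmetric_pair_unchanged(self):
        ep = make_epoch(np.vstack([np.sin(np.arange(100.0)),
                                   -np.sin(np.arange(100.0))]))
        out = rereference_average(ep)
        np.testing.assert_allclose(out.data, ep.data, atol=1e-12)
        again = rereference_average(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_channel_differences_invariant(self):
        rng = np.random.default_rng(3)
        ep = make_epoch(rng.normal(size=(6, 200)))
        out = rereference_average(ep)
        np.testing.assert_allclose(out.data[2] - out.data[5],
                                   ep.data[2] - ep.data[5], atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(make_epoch(np.zeros((1, 10))))


class TestCrop:
    def test_44s_epoch_crops_to_20480_samples(self):
        ep = make_epoch(np.arange(2 * 22528, dtype=float).reshape(2, -1))
        out = crop_stimulation(ep)
        assert out.n_samples == 20480
        # starts exactly at the 2 s sample
        assert out.data[0, 0] == ep.data[0, 1024]

    def test_crop_holds_integer_cycles_of_both_rates(self):
        out = crop_stimulation(make_epoch(np.zeros((2, 22528))))
        assert out.duration_s * 6.0 == 240
        assert out.duration_s * 1.2 == 48

    def test_wrong_duration_rejected(self):
        with pytest.raises(ValueError, match="44"):
            crop_stimulation(make_epoch(np.zeros((2, 20000))))


class TestAveraging:
    def test_identical_epochs_average_to_themselves(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(3, 100))
        eps = [make_epoch(base.copy(), participant=0, notation="n", condition="c")
               for _ in range(4)]
        avg = average_repetitions(eps)[(0, "n", "c")]
        np.testing.assert_allclose(avg.data, base)
        assert avg.labels["n_repetitions"] == 4

    def test_opposite_epochs_cancel(self):
        x = np.random.default_rng(5).normal(size=(2, 50))
        eps = [make_epoch(x, participant=0, notation="n", condition="c"),
               make_epoch(-x, participant=0, notation="n", condition="c")]
        avg = average_repetitions(eps)[(0, "n", "c")]
        np.testing.assert_allclose(avg.data, 0.0, atol=1e-12)

    def test_noise_floor_halves_with_four_repetitions(self):
        """Averaging 4 independent noise epochs drops the spectral floor ~ sqrt(4)."""
        rng = np.random.default_rng(6)
        singles, averaged = [], []
        for _ in range(20):
            eps = [make_epoch(rng.normal(size=(1, 2048)), participant=0,
                              notation="n", condition="c") for _ in range(4)]
            avg = average_repetitions(eps)[(0, "n", "c")]
            floor = lambda d: np.abs(np.fft.rfft(d[0]))[10:900].mean()
            singles.append(floor(eps[0].data))
            averaged.append(floor(avg.data))
        ratio = np.mean(averaged) / np.mean(singles)
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_groups_keyed_by_participant_notation_condition(self):
        eps = [make_epoch(np.ones((2, 10)), participant=p, notation="n",
                          condition=c) for p in (0, 1) for c in ("a", "b")]
        out = average_repetitions(eps)
        assert set(out) == {(0, "n", "a"), (0, "n", "b"), (1, "n", "a"), (1, "n", "b")}

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            average_repetitions([])


class TestFullChain:
    def test_linearity_of_linear_stages(self, montage):
        """chain(signal + noise) == chain(signal) + chain(noise) for the
        filter/resample/re-reference/crop composition."""
        seq = build_sequence(DesignSpec(), seed=1)
        sig = simulate_recording(seq, ResponseSpec(), NoiseSpec(noise_sd_uv=1e-9),
                                 montage, 2048.0, 1)
        noi = simulate_recording(seq, ResponseSpec(standard_amp_uv=0, oddball_amp_uv=0),
                                 NoiseSpec(noise_sd_uv=15.0), montage, 2048.0, 2)
        both = sig.copy()
        both.data = sig.data + noi.data

        def chain(rec):
            return preprocess_recording(rec).data

        np.testing.assert_allclose(chain(both), chain(sig) + chain(noi),
                                   atol=1e-8)

    def test_deterministic_end_to_end(self, clean_recording):
        a = preprocess_recording(clean_recording)
        b = preprocess_recording(clean_recording)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.n_samples == 20480 and a.fs_hz == 512.0

    def test_rejected_recording_returns_none(self, clean_recording):
        rec = clean_recording.copy()
        t = np.arange(rec.n_samples) / rec.fs_hz
        rec.data[5] += 1e4 * np.sin(2 * np.pi * 1.0 * t)  # huge in-band artifact
        assert preprocess_recording(rec) is None
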