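"""EEG cleaning chain: filters, bad channels, wavelets, epoch screening."""

import numpy as np
import pytest
from scipy import signal

from singtrack.audio import BroadbandEnvelope, envelope_from_audio
from singtrack.preprocess import (
    AlignedDataset,
    RawEEG,
    bandpass_final,
    bandpass_raw,
    detect_bad_channels,
    epoch_and_reject,
    epoch_rejection_mask,
    interpolate_channels,
    montage_positions,
    preprocess_pipeline,
    remove_line_noise,
    rereference_average,
    wavelet_denoise,
)
from singtrack.synth import SongSpec, default_kernel, make_song_audio, make_synthetic_eeg

FS = 500.0


def sine(freq, duration=60.0, amp=10.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def raw_from(rows, **kw):
    return RawEEG(np.asarray(rows, dtype=float), sfreq=FS, **kw)


def band_rms(x, fs, lo, hi):
    f, pxx = signal.welch(x, fs=fs, nperseg=int(8 * fs))
    sel = (f >= lo) & (f <= hi)
    return np.sqrt(np.trapezoid(pxx[sel], f[sel]))


class TestBandpassRaw:
    def test_stopband_passband_and_dc(self):
        rng = np.random.default_rng(0)
        slow = sine(0.05, 120.0)
        mid = sine(10.0, 120.0)
        dc = np.full(slow.size, 100.0) + rng.standard_normal(slow.size)
        out = bandpass_raw(raw_from([slow, mid, dc]))
        core = slice(int(15 * FS), int(-15 * FS))
        atten = np.sqrt(np.mean(out.data[0][core] ** 2)) / np.sqrt(np.mean(slow[core] ** 2))
        assert 20 * np.log10(atten) <= -20.0
        keep = np.sqrt(np.mean(out.data[1][core] ** 2)) / np.sqrt(np.mean(mid[core] ** 2))
        assert keep == pytest.approx(1.0, abs=0.05)
        assert np.mean(np.abs(out.data[2][core])) < 1.5  # DC removed, noise remains

    def test_short_recording_raises(self):
        with pytest.raises(ValueError, match="filter length"):
            bandpass_raw(raw_from(np.zeros((2, 1000))))

    def test_log_appended(self):
        out = bandpass_raw(raw_from([sine(5.0), sine(5.0)]))
        assert out.log[-1]["step"] == "bandpass_raw"


class TestLineNoise:
    def _pink(self, rng, n):
        freqs = np.fft.rfftfreq(n, 1 / FS)
        amp = np.zeros_like(freqs)
        amp[1:] = 1 / np.sqrt(freqs[1:])
        return np.fft.irfft(
            amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)), n
        )

    def test_line_component_removed_neighbors_intact(self):
        rng = np.random.default_rng(1)
        n = int(120 * FS)
        base = 5.0 * self._pink(rng, n)
        noisy = base + sine(50.0, 120.0, amp=20.0) + sine(100.0, 120.0, amp=10.0)
        out = remove_line_noise(raw_from([noisy, noisy]))
        for f0 in (50.0, 100.0):
            before = band_rms(noisy, FS, f0 - 0.5, f0 + 0.5)
            after = band_rms(out.data[0], FS, f0 - 0.5, f0 + 0.5)
            assert 20 * np.log10(after / before) <= -15.0
        for lo, hi in ((45, 47.5), (52.5, 55)):
            before = band_rms(noisy, FS, lo, hi)
            after = band_rms(out.data[0], FS, lo, hi)
            assert abs(20 * np.log10(after / before)) < 1.0

    def test_clean_signal_nearly_untouched(self):
        rng = np.random.default_rng(2)
        x = 5.0 * self._pink(rng, int(60 * FS))
        out = remove_line_noise(raw_from([x, x]))
        change = np.sqrt(np.mean((out.data[0] - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert change < 0.02

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            remove_line_noise(raw_from(np.zeros((2, 5000))), freqs=(300.0,))


class TestBadChannels:
    def test_loud_channel_flagged_and_homogeneous_clean(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((16, int(30 * FS)))
        labels = [f"C{i}" for i in range(16)]
        clean = raw_from(data, ch_names=labels)
        assert detect_bad_channels(clean) == set()
        data_bad = data.copy()
        data_bad[5] *= 100.0
        assert detect_bad_channels(raw_from(data_bad, ch_names=labels)) == {"C5"}

    def test_second_pass_peels_masked_outlier(self):
        """A moderate outlier hidden by an extreme one is caught once the
        extreme channel is removed and the z-scores are recomputed."""
        rng = np.random.default_rng(4)
        data = rng.standard_normal((16, int(20 * FS)))
        data[3] *= 1000.0
        data[7] *= 30.0
        assert detect_bad_channels(raw_from(data)) == {"CH03", "CH07"}

    def test_ten_flagged_channels_allowed_on_32(self):
        """No cap on the flagged set: a 32-channel montage may lose 10
        channels without the detector aborting (graded outliers, iterative
        passes at a demonstration threshold)."""
        rng = np.random.default_rng(4)
        data = rng.standard_normal((32, int(20 * FS)))
        data[:10] *= np.geomspace(1e2, 1e9, 10)[::-1][:, None]
        bads = detect_bad_channels(raw_from(data), z_thresh=2.2, passes=6)
        assert bads == {f"CH{i:02d}" for i in range(10)}

    def test_needs_four_channels(self):
        with pytest.raises(ValueError, match="4 channels"):
            detect_bad_channels(raw_from(np.zeros((3, 5000))))


class TestWaveletDenoise:
    def test_clean_sinusoid_nearly_untouched(self):
        x = sine(10.0, 60.0, amp=15.0)
        out = wavelet_denoise(raw_from([x, x]))
        rel = np.sqrt(np.mean((out.data[0] - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert rel < 0.05

    def test_square_pulse_suppressed(self):
        rng = np.random.default_rng(5)
        x = sine(8.0, 60.0, amp=15.0) + rng.standard_normal(int(60 * FS))
        pulse = np.zeros_like(x)
        pulse[10000:10150] = 300.0
        out = wavelet_denoise(raw_from([x + pulse, x]))
        residual = out.data[0] - x
        assert residual[10000:10150].max() < 0.2 * 300.0

    def test_zero_channel_stays_zero(self):
        out = wavelet_denoise(raw_from([np.zeros(4096), np.ones(4096)]))
        assert np.allclose(out.data[0], 0.0)


class TestInterpolation:
    LABELS = ["Fz", "Cz", "Pz", "Oz", "C3", "C4", "F3", "F4", "P3", "P4"]

    def test_constant_field_reproduced(self):
        data = np.full((10, 2000), 7.5)
        raw = raw_from(data, ch_names=self.LABELS)
        out = interpolate_channels(raw, {"Cz"})
        assert np.allclose(out.data[1], 7.5, atol=1e-6)

    def test_smooth_dipolar_field_recovered(self):
        pos = montage_positions(self.LABELS)
        field = pos @ np.array([40.0, 25.0, 60.0])  # linear potential in space
        t = np.arange(2000)
        data = np.outer(field, np.sin(2 * np.pi * t / 500))
        raw = raw_from(data, ch_names=self.LABELS)
        out = interpolate_channels(raw, {"Cz"})
        err = np.max(np.abs(out.data[1] - data[1]))
        assert err < 0.10 * np.ptp(field)

    def test_unknown_bad_label(self):
        raw = raw_from(np.zeros((10, 1000)), ch_names=self.LABELS)
        with pytest.raises(ValueError, match="not in recording"):
            interpolate_channels(raw, {"XX"})


class TestReference:
    def test_zero_mean_and_idempotence(self):
        rng = np.random.default_rng(6)
        labels = ["Fz", "Cz", "Pz", "Oz", "C3", "C4"]
        raw = raw_from(rng.standard_normal((6, 4000)) * 30, ch_names=labels)
        once = rereference_average(raw)
        assert np.max(np.abs(once.data.mean(axis=0))) < 1e-6
        again = rereference_average(
            RawEEG(once.data, once.sfreq, once.ch_names, log=list(once.log))
        )
        assert np.allclose(again.data, once.data)
        assert once.reference == "average"


class TestEpochScreening:
    def _clean_eeg(self, data, labels=None):
        raw = raw_from(data, ch_names=labels)
        return rereference_average(raw)

    def test_pulse_epoch_discarded_quiet_retained(self):
        rng = np.random.default_rng(7)
        n_ep = 20
        data = 20.0 * rng.standard_normal((4, n_ep * 500))
        data[2, 5 * 500 + 100 : 5 * 500 + 250] += 400.0  # 300 ms pulse in epoch 5
        env = BroadbandEnvelope(np.abs(rng.standard_normal(n_ep * 500)), FS)
        ds = epoch_and_reject(self._clean_eeg(data), env, "playsong")
        assert ds.total_epoch_count == n_ep
        assert ds.retained_epoch_count == n_ep - 1
        assert ds.excluded  # fewer than 90 epochs

    def test_all_quiet_epochs_retained(self):
        rng = np.random.default_rng(8)
        keep = epoch_rejection_mask(20.0 * rng.standard_normal((30, 4, 500)), FS)
        assert keep.all()

    def test_ninety_epoch_inclusion_rule(self):
        rng = np.random.default_rng(9)
        for n_ep, excluded in ((89, True), (95, False)):
            data = 10.0 * rng.standard_normal((4, n_ep * 500))
            env = BroadbandEnvelope(np.abs(rng.standard_normal(n_ep * 500)), FS)
            ds = epoch_and_reject(self._clean_eeg(data), env, "lullaby")
            assert ds.excluded is excluded

    def test_span_mismatch_raises(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((4, 5000))
        env = BroadbandEnvelope(np.abs(rng.standard_normal(4000)), FS)
        with pytest.raises(ValueError, match="span"):
            epoch_and_reject(self._clean_eeg(data), env, "playsong")

    def test_rejection_is_permutation_equivariant(self):
        rng = np.random.default_rng(11)
        epochs = 30.0 * rng.standard_normal((40, 4, 500))
        epochs[7, 1, 100:300] += 400.0
        epochs[22, 3, 50:200] += 400.0
        keep = epoch_rejection_mask(epochs, FS)
        perm = rng.permutation(40)
        assert np.array_equal(epoch_rejection_mask(epochs[perm], FS), keep[perm])


class TestFinalBandpass:
    def _dataset(self, freq):
        n_ep = 10
        t = np.arange(n_ep * 500) / FS
        x = 10.0 * np.sin(2 * np.pi * freq * t)
        epochs = x.reshape(n_ep, 1, 500).repeat(2, axis=1)
        env = np.abs(np.sin(t)).reshape(n_ep, 500)
        return AlignedDataset(epochs=epochs, envelope_segments=env, condition="playsong", ch_names=["Cz", "Fz"])

    def test_passband_and_stopband(self):
        mid = bandpass_final(self._dataset(5.0))
        core = slice(100, 400)
        ratio = np.sqrt(np.mean(mid.epochs[5, 0, core] ** 2)) / (10.0 / np.sqrt(2))
        assert ratio == pytest.approx(1.0, abs=0.05)
        high = bandpass_final(self._dataset(40.0))
        atten = np.sqrt(np.mean(high.epochs[5, 0, core] ** 2)) / (10.0 / np.sqrt(2))
        assert 20 * np.log10(atten) <= -20.0

    def test_empty_dataset_passthrough(self):
        ds = AlignedDataset(
            epochs=np.empty((0, 2, 500)),
            envelope_segments=np.empty((0, 500)),
            condition="lullaby",
            ch_names=["Cz", "Fz"],
        )
        assert bandpass_final(ds).n_epochs == 0


class TestPipeline:
    def test_end_to_end_artifact_handling_and_log(self):
        """Every injected >=150 uV transient is either attenuated below the
        rejection threshold by wavelet denoising or its epoch is dropped."""
        audio = make_song_audio(SongSpec.for_condition("playsong", seed=31), duration_s=45)
        env = envelope_from_audio(audio)
        kernel = default_kernel(8, snr=1.0)
        raw = make_synthetic_eeg(env, kernel, n_channels=8, artifact_rate=8.0, seed=32)
        spans = raw.meta["ground_truth"]["artifact_spans"]
        assert spans, "test needs at least one artifact"
        ds = preprocess_pipeline(raw, env, "playsong")
        steps = [entry["step"] for entry in ds.log]
        assert steps[:2] == ["bandpass_raw", "remove_line_noise"]
        assert "wavelet_denoise" in steps and "epoch_and_reject" in steps
        # reconstruct which epochs survived via the envelope segments
        env_ep = env.values[: ds.total_epoch_count * 500].reshape(-1, 500)
        surviving = {tuple(np.round(seg, 9)) for seg in ds.envelope_segments}
        for start, stop in spans:
            for ep in range(start // 500, (max(stop - 1, start)) // 500 + 1):
                if ep >= ds.total_epoch_count:
                    continue
                key = tuple(np.round(env_ep[ep], 9))
                if key in surviving:
                    idx = next(
                        i for i, seg in enumerate(ds.envelope_segments)
                        if tuple(np.round(seg, 9)) == key
                    )
                    window_max = np.abs(ds.epochs[idx]).max()
                    assert window_max < 150.0, "artifact neither dropped nor attenuated"
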