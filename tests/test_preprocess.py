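import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch

from eventconn.connectivity import BandSpec, detect_events
from eventconn.preprocess import (
    Recording,
    SegmentAnnotation,
    bandpass,
    load_channel_metadata,
    load_recording,
    notch_60hz,
    resample_to_1khz,
    select_segments,
)


def sine_recording(freq, fs, duration=4.0, amp=1.0, n_channels=1):
    t = np.arange(0, duration, 1 / fs)
    x = amp * np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(x, (n_channels, 1)), fs,
                     [f"ch{i}" for i in range(n_channels)])


def make_metadata(labels, **overrides):
    n = len(labels)
    base = {
        "label": labels,
        "x_mm": np.arange(n, dtype=float), "y_mm": 0.0, "z_mm": 0.0,
        "region": "M", "soz": 0, "hemisphere": "L",
        "gray_matter": 1, "noise_free": 1,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestLoadRecording:
    def test_gray_matter_flag_filters_channels(self, tmp_path, rng):
        data = rng.standard_normal((3, 1000))
        path = tmp_path / "rec.tsv"
        np.savetxt(path, data, delimiter="\t")
        meta = make_metadata(["a", "b", "c"], gray_matter=[1, 0, 1])
        rec = load_recording(path, meta, fs=1000)
        assert rec.channel_labels == ["a", "c"]
        assert rec.n_channels == 2

    def test_roundtrip_preserves_values(self, tmp_path, rng):
        data = rng.standard_normal((2, 500))
        path = tmp_path / "rec.tsv"
        np.savetxt(path, data, delimiter="\t")
        rec = load_recording(path, make_metadata(["a", "b"]), fs=1000)
        np.testing.assert_allclose(rec.data, data, rtol=1e-10)

    def test_metadata_file_mismatch_is_an_error(self, tmp_path, rng):
        path = tmp_path / "rec.tsv"
        np.savetxt(path, rng.standard_normal((2, 100)), delimiter="\t")
        meta = make_metadata(["a", "b", "XX1"])
        with pytest.raises(ValueError):
            load_recording(path, meta, fs=1000)

    def test_metadata_schema_validated(self, tmp_path):
        bad = tmp_path / "meta.tsv"
        pd.DataFrame({"label": ["a"]}).to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_channel_metadata(bad)


class TestResample:
    def test_1khz_input_is_identity(self):
        rec = sine_recording(40, 1000)
        out = resample_to_1khz(rec)
        assert out is rec

    def test_downsampling_attenuates_above_output_nyquist(self):
        rec = sine_recording(700, 2000)
        out = resample_to_1khz(rec)
        assert out.fs == 1000.0
        atten_db = 20 * np.log10(out.data.std() / rec.data.std())
        assert atten_db <= -40.0

    def test_downsampling_preserves_passband(self):
        rec = sine_recording(40, 2000)
        out = resample_to_1khz(rec)
        assert out.data.std() / rec.data.std() == pytest.approx(1.0, abs=0.02)

    def test_upsampled_low_rate_recording_keeps_spectral_peak(self):
        # a 40 Hz tone sampled at 200 Hz, brought up to 1 kHz
        rec = sine_recording(40, 200, duration=10.0, amp=50.0)
        out = resample_to_1khz(rec)
        assert out.fs == 1000.0
        f, p = welch(out.data[0], fs=1000, nperseg=4096)
        assert abs(f[np.argmax(p)] - 40.0) < 1.0

    def test_upsampling_changes_event_counts_only_marginally(self):
        # band-limited low-gamma content: cycle peaks survive the resampling
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 1 / 1000)
        x = 50 * np.sin(2 * np.pi * 40 * t) + 5 * rng.standard_normal(t.size)
        band = BandSpec("low_gamma", 30, 55)
        native = bandpass(Recording(x[None, ::1], 1000, ["a"]), band)
        low = Recording(x[None, ::5], 200, ["a"])  # decimated acquisition
        up = bandpass(resample_to_1khz(low), band)
        n_native = len(detect_events(native.data[0]))
        n_up = len(detect_events(up.data[0]))
        assert abs(n_native - n_up) / n_native < 0.10

    def test_channel_order_preserved(self, rng):
        rec = Recording(rng.standard_normal((3, 4000)), 2000, ["z", "a", "m"])
        out = resample_to_1khz(rec)
        assert out.channel_labels == ["z", "a", "m"]


class TestNotch:
    def test_60hz_suppressed(self):
        out = notch_60hz(sine_recording(60, 1000, duration=10.0))
        # steady state away from the filter's edge transients
        assert out.data[0, 1000:-1000].std() / 0.7071 < 0.032  # >= 30 dB

    @pytest.mark.parametrize("freq", [40, 80])
    def test_neighbouring_frequencies_preserved(self, freq):
        out = notch_60hz(sine_recording(freq, 1000))
        assert out.data.std() / 0.7071 > 0.891  # < 1 dB loss

    def test_broadband_power_outside_notch_preserved(self, rng):
        x = rng.standard_normal(30000)
        out = notch_60hz(Recording(x[None, :], 1000, ["a"]))
        f, p_in = welch(x, fs=1000, nperseg=2048)
        _, p_out = welch(out.data[0], fs=1000, nperseg=2048)
        keep = (f > 2) & ((f < 55) | (f > 65)) & (f < 480)
        ratio = p_out[keep].sum() / p_in[keep].sum()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestBandpass:
    def test_passband_gain(self, low_gamma):
        out = bandpass(sine_recording(40, 1000), low_gamma)
        assert out.data.std() / 0.7071 == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation(self, low_gamma):
        out = bandpass(sine_recording(10, 1000), low_gamma)
        assert 20 * np.log10(out.data.std() / 0.7071) < -40

    def test_zero_phase_impulse_response_is_symmetric(self, low_gamma):
        x = np.zeros((1, 4001))
        x[0, 2000] = 1.0
        out = bandpass(Recording(x, 1000, ["a"]), low_gamma).data[0]
        np.testing.assert_allclose(out, out[::-1], atol=1e-9)

    def test_resample_then_bandpass_commutes_with_native_processing(self):
        t = np.arange(0, 10, 1 / 2000)
        x = np.sin(2 * np.pi * 40 * t)
        band = BandSpec("low_gamma", 30, 55)
        via_resample = bandpass(
            resample_to_1khz(Recording(x[None, :], 2000, ["a"])), band)
        native = bandpass(Recording(x[None, ::2], 1000, ["a"]), band)
        # compare away from the edges
        a = via_resample.data[0, 2000:-2000]
        b = native.data[0, 2000:-2000]
        assert np.corrcoef(a, b)[0, 1] > 0.999

    def test_band_edges_validated(self):
        rec = sine_recording(40, 1000)
        with pytest.raises(ValueError):
            bandpass(rec, BandSpec("bad", 300, 499))


class TestSegments:
    def test_metadata_driven_selection(self):
        rec = sine_recording(10, 1000, duration=600.0)
        segs = [
            SegmentAnnotation(0, 60000, "quiet_wakefulness",
                              {"post_implant_hours": 30,
                               "hours_to_next_seizure": 10}),
            SegmentAnnotation(60000, 60000, "sleep",
                              {"post_implant_hours": 30}),
            SegmentAnnotation(120000, 60000, "quiet_wakefulness",
                              {"post_implant_hours": 10}),
            SegmentAnnotation(180000, 60000, "quiet_wakefulness",
                              {"hours_to_next_seizure": 2}),
        ]
        kept = select_segments(segs, rec)
        assert len(kept) == 1 and kept[0].onset_ms == 0

    def test_segment_beyond_recording_rejected(self):
        rec = sine_recording(10, 1000, duration=1.0)
        with pytest.raises(ValueError):
            select_segments([SegmentAnnotation(0, 5000, "quiet_wakefulness")],
                            rec)
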