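"""Windowing, Butterworth decomposition, normalization, channel selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegfuse as ef
from eegfuse.preprocessing import band_name, combination_indices


def _recording(n_channels=4, fs=128.0, duration=30.0, label=0, seed=0, channels=None):
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    channels = channels or tuple(f"CH{i}" for i in range(n_channels))
    return ef.Recording(
        data=rng.standard_normal((len(channels), n)),
        fs=fs,
        channels=channels,
        label=label,
        subject_id="S00",
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_window_matrix_shapes(self):
        """10-s windows: 2000 x 62 at 200 Hz and 1280 x 32 at 128 Hz."""
        rec_a = _recording(n_channels=62, fs=200.0, duration=12.0)
        segs = ef.segment_recording(rec_a)
        assert segs[0].data.shape == (2000, 62)
        rec_b = _recording(n_channels=32, fs=128.0, duration=12.0)
        assert ef.segment_recording(rec_b)[0].data.shape == (1280, 32)

    def test_exact_window_gives_single_segment(self):
        rec = _recording(duration=10.0)
        segs = ef.segment_recording(rec)
        assert len(segs) == 1 and segs[0].start_s == 0.0

    def test_thirty_seconds_gives_eleven_segments(self):
        # brute-force oracle: valid start offsets 0, 2, ..., 20 s
        rec = _recording(fs=128.0, duration=30.0, label=1)
        segs = ef.segment_recording(rec, window_s=10.0, step_s=2.0)
        offsets = [s.start_s for s in segs]
        expected = [o for o in range(0, 31, 2) if o + 10 <= 30]
        assert offsets == pytest.approx(expected)
        assert len(segs) == 11
        assert all(s.label == 1 for s in segs)

    def test_too_short_recording_raises(self):
        rec = _recording(duration=8.0)
        with pytest.raises(ef.RecordingTooShortError):
            ef.segment_recording(rec, window_s=10.0)

    def test_count_matches_brute_force_enumeration(self):
        """1000 random (n_samples, window, step) triples vs enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 5000))
            w = int(rng.integers(1, 3000))
            s = int(rng.integers(1, 500))
            brute = sum(1 for start in range(0, n, s) if start + w <= n and start % s == 0)
            assert ef.segment_count(n, w, s) == brute

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        dur=st.floats(10.0, 60.0),
        step=st.floats(0.5, 5.0),
    )
    def test_segment_starts_cover_recording(self, dur, step):
        rec = _recording(n_channels=2, fs=64.0, duration=dur)
        segs = ef.segment_recording(rec, window_s=10.0, step_s=step)
        n_window = int(round(10.0 * rec.fs))
        n_step = int(round(step * rec.fs))
        assert n_step >= 1
        # last segment still fits; one more would overrun
        last = int(round(segs[-1].start_s * rec.fs))
        assert last + n_window <= rec.n_samples
        assert last + n_step + n_window > rec.n_samples


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

class TestBandpass:
    def test_gamma_band_edges(self):
        spec = ef.design_bandpass(ef.BANDS["gamma"], fs=200.0)
        assert (spec.band.f1, spec.band.f2) == (31.0, 50.0)
        assert spec.order == 4

    def test_band_center_magnitude(self):
        for band in ef.BANDS.values():
            spec = ef.design_bandpass(band, fs=512.0)
            center = np.sqrt(band.f1 * band.f2)
            assert spec.magnitude(np.array([center]))[0] >= 0.95

    def test_nyquist_violation(self):
        with pytest.raises(ef.NyquistError):
            ef.design_bandpass(ef.BANDS["gamma"], fs=100.0)

    def test_sine_routed_to_beta(self):
        """A 20 Hz unit tone lands in beta (>=0.9) and not delta (<=0.05)."""
        fs, dur = 200.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 20.0 * t)[None, :]
        out = ef.decompose_bands(x, fs)
        mid = slice(int(2 * fs), int(18 * fs))  # steady state
        amp = {b: np.sqrt(2) * np.std(y[0, mid]) for b, y in out.items()}
        assert amp["beta"] >= 0.9
        assert amp["delta"] <= 0.05

    def test_all_five_bands_returned(self):
        out = ef.decompose_bands(np.zeros((3, 500)), fs=256.0)
        assert set(out) == {"delta", "theta", "alpha", "beta", "gamma"}
        for y in out.values():
            assert np.allclose(y, 0.0)
            assert y.shape == (3, 500)

    def test_nan_input_rejected(self):
        x = np.zeros((2, 500))
        x[0, 10] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ef.decompose_bands(x, fs=256.0)

    def test_gamma_skippable_at_low_fs(self):
        out = ef.decompose_bands(np.zeros((1, 400)), fs=90.0, skip_unresolvable=True)
        assert "gamma" not in out and "beta" in out
        with pytest.raises(ef.NyquistError):
            ef.decompose_bands(np.zeros((1, 400)), fs=90.0)

    def test_decomposition_is_linear(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 1000))
        y = rng.standard_normal((2, 1000))
        a, b = 1.7, -0.4
        left = ef.decompose_bands(a * x + b * y, fs=256.0)
        fx = ef.decompose_bands(x, fs=256.0)
        fy = ef.decompose_bands(y, fs=256.0)
        for band in left:
            assert np.allclose(left[band], a * fx[band] + b * fy[band], atol=1e-8)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        x = 3.0 + 2.5 * rng.standard_normal((4, 600))
        y = ef.normalize_band(x)
        assert np.all(np.abs(y.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(y.std(axis=1) - 1.0) < 1e-6)

    def test_known_values(self):
        # population sd of [1,2,3,4] is sqrt(5)/2 = 1.1180
        y = ef.normalize_band(np.array([[1.0, 2.0, 3.0, 4.0]]))
        expected = [-1.3416407865, -0.4472135955, 0.4472135955, 1.3416407865]
        assert y[0] == pytest.approx(expected, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 500))
        once = ef.normalize_band(x)
        twice = ef.normalize_band(once)
        assert np.allclose(once, twice, atol=1e-6)

    def test_flat_channel_named(self):
        x = np.ones((2, 100))
        x[1] = np.arange(100)
        with pytest.raises(ef.FlatChannelError, match="T7"):
            ef.normalize_band(x, channels=("T7", "T8"))


# ---------------------------------------------------------------------------
# Channel combinations
# ---------------------------------------------------------------------------

MONTAGE_62ISH = tuple(
    list(ef.DEFAULT_MONTAGE_32) + [f"X{i}" for i in range(30)]
)


class TestChannelSelection:
    def test_c1_has_six_channels(self):
        data = np.zeros((100, len(MONTAGE_62ISH)))
        out = ef.select_channels(data, MONTAGE_62ISH, "C1")
        assert out.shape == (100, 6)

    def test_c3_order(self):
        assert ef.COMBINATIONS["C3"].labels == ("T7", "P7", "CP5", "T8", "P8", "CP6")
        idx = combination_indices(ef.DEFAULT_MONTAGE_32, "C3")
        picked = [ef.DEFAULT_MONTAGE_32[i] for i in idx]
        assert picked == ["T7", "P7", "CP5", "T8", "P8", "CP6"]

    def test_all_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((50, 32))
        out = ef.select_channels(data, ef.DEFAULT_MONTAGE_32, "All")
        assert np.array_equal(out, data)
        # selecting after All equals selecting directly
        via_all = ef.select_channels(out, ef.DEFAULT_MONTAGE_32, "C2")
        direct = ef.select_channels(data, ef.DEFAULT_MONTAGE_32, "C2")
        assert np.array_equal(via_all, direct)

    def test_missing_channels_listed(self):
        montage = ("FT7", "T7", "TP7")  # lacks the right hemisphere
        with pytest.raises(ef.MissingChannelsError, match="C5"):
            ef.select_channels(np.zeros((10, 3)), montage, "C2")

    def test_case_insensitive_matching(self):
        montage = ("ft7", " FT8 ", "t7", "T8", "tp7", "TP8")
        idx = combination_indices(montage, "C1")
        assert list(idx) == [0, 1, 2, 3, 4, 5]


# ---------------------------------------------------------------------------
# Dataset preprocessing
# ---------------------------------------------------------------------------

class TestPreprocessDataset:
    def test_two_recordings_give_22_segments(self):
        recs = [
            _recording(n_channels=4, fs=128.0, duration=30.0, label=-1, seed=i)
            for i in range(2)
        ]
        tensor = ef.preprocess_dataset(recs)
        assert tensor.n_segments == 22
        assert tensor.manifest["n_segments"].sum() == 22

    def test_single_window_recording(self):
        rec = _recording(duration=10.0, label=1)
        tensor = ef.preprocess_dataset([rec])
        assert tensor.n_segments == 1
        assert tensor.labels.tolist() == [2]  # raw +1 -> class 2

    def test_label_mapping(self):
        recs = [
            _recording(duration=10.0, label=lab, seed=lab + 5)
            for lab in (-1, 0, 1)
        ]
        tensor = ef.preprocess_dataset(recs)
        assert sorted(tensor.labels.tolist()) == [0, 1, 2]

    def test_mixed_sampling_rates_rejected(self):
        recs = [_recording(fs=128.0, duration=10.0), _recording(fs=200.0, duration=10.0)]
        with pytest.raises(ValueError, match="sampling rate"):
            ef.preprocess_dataset(recs)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ef.preprocess_dataset([])

    def test_band_tensor_shapes_aligned(self, c1_tensor):
        n = c1_tensor.n_segments
        for b, arr in c1_tensor.data.items():
            assert arr.shape == (n, 1280, 6)
        assert c1_tensor.labels.shape == (n,)
        assert c1_tensor.subjects.shape == (n,)

    def test_subject_scope_preserves_class_power(self, c1_tensor):
        """Subject-pooled z-scoring keeps gamma power ordered by class."""
        g = c1_tensor.data["gamma"]
        power = (g.astype(np.float64) ** 2).mean(axis=(1, 2))
        by_class = [power[c1_tensor.labels == c].mean() for c in range(3)]
        assert by_class[0] < by_class[1] < by_class[2]


def test_band_name_normalization():
    assert band_name("β") == "beta"
    assert band_name(" Gamma ") == "gamma"
    with pytest.raises(KeyError):
        band_name("mu")
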