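import numpy as np
import pytest

from harfusion.signal_core import AccelSegment
from harfusion.reconstruction import (IMAGE_SIZE, MultiChannelPlotImager, RPConfig,
                                      RecurrencePlotImager, ReconImage,
                                      SeriesTooShortError, SpectrogramConfig,
                                      SpectrogramImager, block_average, load_png,
                                      mp_encode, mp_image, mp_scale, reconstruct_all,
                                      rp_image, rp_matrix, save_png,
                                      spectrogram_image, spectrogram_matrix,
                                      stft_magnitude)


def naive_stft_power(series, fs, cfg):
    """Frame-by-frame DFT oracle: independent of the FFT-based implementation."""
    length = int(round(cfg.window_seconds * fs))
    hop = max(1, int(round(length * (1 - cfg.overlap_fraction))))
    if cfg.window in ("rectangular", "boxcar"):
        win = np.ones(length)
    else:
        from scipy.signal import get_window
        win = get_window(cfg.window, length)
    n_frames = (len(series) - length) // hop + 1
    n_bins = length // 2 + 1
    out = np.zeros((n_bins, n_frames))
    for m in range(n_frames):
        frame = series[m * hop:m * hop + length] * win
        for w in range(n_bins):
            coeff = np.sum(frame * np.exp(-2j * np.pi * w * np.arange(length) / length))
            out[w, m] = np.abs(coeff) ** 2
    return out


class TestSTFT:
    @pytest.mark.parametrize("n,window_s,overlap,expected_frames", [
        (2500, 5, 0.5, 3),     # L=1250, H=625
        (2500, 10, 0.5, 1),    # single frame
        (2500, 1, 0.5, 19),    # L=250, H=125
        (2500, 2, 0.5, 9),
    ])
    def test_frame_count_formula(self, n, window_s, overlap, expected_frames, rng):
        series = rng.normal(0, 1, n)
        cfg = SpectrogramConfig(window_seconds=window_s, overlap_fraction=overlap)
        spec = stft_magnitude(series, 250, cfg)
        length = window_s * 250
        assert spec.shape == (length // 2 + 1, expected_frames)

    def test_zero_series_gives_zero_matrix(self):
        cfg = SpectrogramConfig(window_seconds=1)
        spec = stft_magnitude(np.zeros(1000), 250, cfg)
        assert np.all(spec == 0)

    def test_pure_sinusoid_peaks_at_its_bin(self):
        t = np.arange(2500) / 250
        series = np.sin(2 * np.pi * 10 * t)
        cfg = SpectrogramConfig(window_seconds=1, window="rectangular")
        spec = stft_magnitude(series, 250, cfg)
        assert np.all(spec.argmax(axis=0) == 10)

    @pytest.mark.parametrize("window", ["rectangular", "hann"])
    def test_matches_naive_dft_oracle(self, rng, window):
        series = rng.normal(0, 1, 64)
        cfg = SpectrogramConfig(window_seconds=32 / 250, overlap_fraction=0.5,
                                window=window)
        ours = stft_magnitude(series, 250, cfg)
        oracle = naive_stft_power(series, 250, cfg)
        assert ours.shape == oracle.shape
        np.testing.assert_allclose(ours, oracle, rtol=1e-8, atol=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(SeriesTooShortError):
            stft_magnitude(np.zeros(100), 250, SpectrogramConfig(window_seconds=1))


class TestSpectrogramImage:
    def test_zero_segment_uniform_image(self):
        # a zero signal has an all-floor dB stack -> one colormap entry;
        # a non-zero constant would instead show its DC line
        seg = AccelSegment(np.zeros((2500, 3)))
        img = spectrogram_image(seg)
        assert len(np.unique(img.pixels.reshape(-1, 3), axis=0)) == 1

    def test_stacked_width_is_three_frames_per_axis(self, make_segment):
        seg = make_segment()
        mat = spectrogram_matrix(seg, SpectrogramConfig(window_seconds=10))
        assert mat.shape == (1251, 3)  # single-frame degenerate case: width 3x1
        mat5 = spectrogram_matrix(seg, SpectrogramConfig(window_seconds=5))
        assert mat5.shape == (626, 9)  # 3 frames x 3 axes

    def test_output_invariants(self, make_segment):
        img = spectrogram_image(make_segment())
        assert img.pixels.shape == (IMAGE_SIZE, IMAGE_SIZE, 3)
        assert img.pixels.dtype == np.uint8
        assert img.method == "spectrogram"


class TestRecurrencePlot:
    def test_three_point_series_exact_matrix(self):
        d = rp_matrix(np.array([0.0, 1.0, 2.0]), RPConfig(downsample_length=3))
        np.testing.assert_array_equal(d, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_symmetry_and_zero_diagonal_vs_bruteforce(self, rng):
        series = rng.normal(0, 100, 16)
        d = rp_matrix(series, RPConfig(downsample_length=16))
        oracle = np.array([[abs(a - b) for b in series] for a in series])
        np.testing.assert_allclose(d, oracle)
        np.testing.assert_array_equal(d, d.T)
        np.testing.assert_array_equal(np.diag(d), np.zeros(16))

    def test_constant_axis_channel_is_zero(self, rng):
        samples = rng.normal(0, 100, (2500, 3))
        samples[:, 1] = 3.0  # constant y axis
        img = rp_image(AccelSegment(samples))
        assert np.all(img.pixels[:, :, 1] == 0)
        assert img.pixels[:, :, 0].max() > 0

    def test_translation_invariance(self, make_segment):
        seg = make_segment()
        shifted = AccelSegment(seg.samples + 1234.5, fs=seg.fs,
                               subject_id=seg.subject_id, label=seg.label)
        np.testing.assert_array_equal(rp_image(seg).pixels, rp_image(shifted).pixels)

    def test_block_average_downsamples(self):
        out = block_average(np.arange(10.0), 5)
        np.testing.assert_allclose(out, [0.5, 2.5, 4.5, 6.5, 8.5])
        short = block_average(np.arange(4.0), 10)
        np.testing.assert_array_equal(short, np.arange(4.0))


class TestMultiChannelPlot:
    def test_digit_decomposition_example(self):
        r, g, b = mp_encode(np.array([123.4567]))
        assert (r[0], g[0], b[0]) == (123, 45, 67)

    def test_scaling_endpoints(self, rng):
        samples = rng.normal(0, 500, (2500, 3))
        scaled = mp_scale(samples)
        idx_min = np.unravel_index(samples.argmin(), samples.shape)
        idx_max = np.unravel_index(samples.argmax(), samples.shape)
        assert scaled[idx_min] == 0.0
        assert scaled[idx_max] == 255.0
        r, g, b = mp_encode(scaled.ravel())
        flat_min = np.ravel_multi_index(idx_min, samples.shape)
        flat_max = np.ravel_multi_index(idx_max, samples.shape)
        assert (r[flat_min], g[flat_min], b[flat_min]) == (0, 0, 0)
        assert (r[flat_max], g[flat_max], b[flat_max]) == (255, 0, 0)

    def test_round_trip_within_1e_minus_4(self, rng):
        values = rng.uniform(0, 255, 10_000)
        r, g, b = mp_encode(values)
        rebuilt = r + g / 100 + b / 1e4
        assert np.max(np.abs(values - rebuilt)) < 1e-4

    def test_constant_segment_all_black(self):
        img = mp_image(AccelSegment(np.full((2500, 3), 9.9)))
        assert np.all(img.pixels == 0)

    def test_output_invariants(self, make_segment):
        img = mp_image(make_segment())
        assert img.pixels.shape == (IMAGE_SIZE, IMAGE_SIZE, 3)
        assert img.pixels.dtype == np.uint8


class TestReconstructAll:
    def test_fixed_order_and_shapes(self, make_segment):
        triple = reconstruct_all(make_segment())
        assert [i.method for i in triple] == ["spectrogram", "rp", "mp"]
        for img in triple:
            assert img.pixels.shape == (IMAGE_SIZE, IMAGE_SIZE, 3)

    def test_deterministic(self, make_segment):
        seg = make_segment()
        a = reconstruct_all(seg)
        b = reconstruct_all(seg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_imagers_batch_shapes(self, make_segment):
        segs = [make_segment() for _ in range(3)]
        for imager in (SpectrogramImager(), RecurrencePlotImager(),
                       MultiChannelPlotImager()):
            out = imager.fit_transform(segs)
            assert out.shape == (3, IMAGE_SIZE, IMAGE_SIZE, 3)
            assert out.dtype == np.uint8

    def test_png_roundtrip(self, make_segment, tmp_path):
        img = rp_image(make_segment())
        save_png(tmp_path / "x.png", img)
        loaded = load_png(tmp_path / "x.png", method="rp")
        np.testing.assert_array_equal(loaded.pixels, img.pixels)


def test_recon_image_validates_shape_and_dtype():
    with pytest.raises(ValueError):
        ReconImage(np.zeros((32, 32, 3), dtype=np.uint8), "rp")
    with pytest.raises(ValueError):
        ReconImage(np.zeros((64, 64, 3), dtype=np.float64), "rp")
    with pytest.raises(ValueError):
        ReconImage(np.zeros((64, 64, 3), dtype=np.uint8), "wavelet")
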