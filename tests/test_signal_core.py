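import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from harfusion.signal_core import (AccelSegment, DEFAULT_TAXONOMY, EmptyDatasetError,
                                   InsufficientSubjectsError, NegativeSigmaError,
                                   NonFiniteSignalError, add_gaussian_noise,
                                   dataset_sigma, frame_to_segments,
                                   load_segments_npz, save_segments_npz,
                                   segment_signal, segments_to_frame,
                                   split_by_subject)


class TestSegmentSignal:
    @pytest.mark.parametrize("n_in,expected", [(7500, 3), (2250, 0), (6250, 2)])
    def test_window_count(self, rng, n_in, expected):
        stream = rng.normal(0, 1, size=(n_in, 3))
        segs = segment_signal(stream, fs=250, segment_seconds=10)
        assert len(segs) == expected
        assert all(s.samples.shape == (2500, 3) for s in segs)

    def test_trailing_remainder_discarded_and_concat_identity(self, rng):
        stream = rng.normal(0, 1, size=(6250, 3))
        segs = segment_signal(stream, fs=250, segment_seconds=10)
        rebuilt = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(rebuilt, stream[:5000])

    @settings(derandomize=True, max_examples=20)
    @given(n=st.integers(0, 50), fs=st.sampled_from([2, 5, 10]))
    def test_concatenation_property(self, n, fs):
        rng = np.random.default_rng(n * 31 + fs)
        stream = rng.normal(0, 1, size=(n, 3))
        segs = segment_signal(stream, fs=fs, segment_seconds=1)
        assert len(segs) == n // fs
        if segs:
            rebuilt = np.concatenate([s.samples for s in segs])
            np.testing.assert_array_equal(rebuilt, stream[:len(segs) * fs])

    def test_non_finite_rejected(self):
        stream = np.zeros((100, 3))
        stream[3, 1] = np.nan
        with pytest.raises(NonFiniteSignalError):
            segment_signal(stream, fs=10, segment_seconds=1)

    def test_metadata_propagates(self, rng):
        segs = segment_signal(rng.normal(0, 1, (20, 3)), fs=10, segment_seconds=1,
                              subject_id="S007", label="WK")
        assert [s.segment_index for s in segs] == [0, 1]
        assert all(s.subject_id == "S007" and s.label == "WK" for s in segs)


class TestSplitBySubject:
    def test_study_scale_partition_sizes(self, rng):
        # 210 subjects x 75 segments; a 0.2 test fraction reserves 42 subjects
        # = 3150 segments and leaves 12,600 for training+validation
        segs = [AccelSegment(rng.normal(0, 1, (5, 3)), fs=5.0,
                             subject_id=f"S{s:03d}", label="WK", segment_index=i)
                for s in range(210) for i in range(75)]
        split = split_by_subject(segs, test_fraction=0.2, val_fraction=0.2, seed=3)
        assert len(split.test) == 3150
        assert len(split.train) + len(split.validation) == 12600

    def test_deterministic_given_seed(self, tiny_segments):
        segs = tiny_segments()
        a = split_by_subject(segs, 0.25, 0.25, seed=9)
        b = split_by_subject(segs, 0.25, 0.25, seed=9)
        assert a.subjects("test") == b.subjects("test")
        assert a.subjects("validation") == b.subjects("validation")

    def test_subject_disjointness_many_seeds(self, tiny_segments):
        segs = tiny_segments()
        for seed in range(100):
            split = split_by_subject(segs, 0.25, 0.25, seed=seed)
            trainval = split.subjects("train") | split.subjects("validation")
            assert not trainval & split.subjects("test")
            assert not split.subjects("train") & split.subjects("validation")

    def test_partitions_exhaustive_over_segments(self, tiny_segments):
        segs = tiny_segments()
        split = split_by_subject(segs, 0.25, 0.25, seed=1)
        assert len(split.train) + len(split.validation) + len(split.test) == len(segs)

    def test_too_few_subjects(self, tiny_segments):
        with pytest.raises(InsufficientSubjectsError):
            split_by_subject(tiny_segments(n_subjects=2), 0.3, 0.3, seed=0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_invalid_test_fraction(self, tiny_segments, bad):
        with pytest.raises(ValueError):
            split_by_subject(tiny_segments(), test_fraction=bad, seed=0)


class TestGaussianNoise:
    def test_sigma_zero_is_identity(self, make_segment):
        seg = make_segment()
        out = add_gaussian_noise(seg, 0.0, seed=4)
        np.testing.assert_array_equal(out.samples, seg.samples)

    def test_noise_std_matches_sigma(self, make_segment):
        # the 50 % level of a pooled sigma of 550.94
        seg = make_segment()
        out = add_gaussian_noise(seg, 275.0, seed=4)
        resid = (out.samples - seg.samples).ravel()
        assert abs(resid.std() - 275.0) / 275.0 < 0.05

    def test_same_seed_bit_identical(self, make_segment):
        seg = make_segment()
        a = add_gaussian_noise(seg, 55.0, seed=11)
        b = add_gaussian_noise(seg, 55.0, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_metadata_and_input_preserved(self, make_segment):
        seg = make_segment(subject_id="S042", label="FF")
        original = seg.samples.copy()
        out = add_gaussian_noise(seg, 110.0, seed=0)
        np.testing.assert_array_equal(seg.samples, original)
        assert (out.fs, out.subject_id, out.label) == (seg.fs, "S042", "FF")
        assert out.samples.shape == seg.samples.shape

    def test_negative_sigma_rejected(self, make_segment):
        with pytest.raises(NegativeSigmaError):
            add_gaussian_noise(make_segment(), -1.0, seed=0)


class TestDatasetSigma:
    def test_constant_dataset_is_zero(self):
        seg = AccelSegment(np.full((10, 3), 7.0), fs=10.0)
        assert dataset_sigma([seg]) == 0.0

    def test_standard_normal_draws(self, rng):
        segs = [AccelSegment(rng.standard_normal((2500, 3)), fs=250.0)
                for _ in range(14)]  # > 1e5 values
        assert abs(dataset_sigma(segs) - 1.0) < 0.02

    def test_matches_two_pass_oracle(self, rng):
        values = rng.normal(3.0, 2.5, size=99)
        seg = AccelSegment(values.reshape(-1, 3), fs=33.0)
        pooled = seg.samples.ravel()
        mean = pooled.sum() / pooled.size
        oracle = np.sqrt(((pooled - mean) ** 2).sum() / pooled.size)
        assert abs(dataset_sigma([seg]) - oracle) < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(EmptyDatasetError):
            dataset_sigma([])


class TestStorage:
    def test_npz_roundtrip(self, tiny_segments, tmp_path):
        segs = tiny_segments(n_subjects=3)
        path = tmp_path / "segs.npz"
        save_segments_npz(path, segs)
        loaded = load_segments_npz(path)
        assert len(loaded) == len(segs)
        for a, b in zip(segs, loaded):
            np.testing.assert_array_equal(a.samples, b.samples)
            assert (a.subject_id, a.label, a.segment_index) == \
                   (b.subject_id, b.label, b.segment_index)

    def test_npz_bytes_deterministic(self, tiny_segments, tmp_path):
        segs = tiny_segments(n_subjects=3)
        p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
        save_segments_npz(p1, segs)
        save_segments_npz(p2, segs)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_frame_roundtrip(self, tiny_segments):
        segs = tiny_segments(n_subjects=3)
        df = segments_to_frame(segs)
        assert list(df.columns) == ["subject_id", "label", "segment_index",
                                    "sample_index", "ax", "ay", "az"]
        loaded = frame_to_segments(df, fs=5.0)
        assert len(loaded) == len(segs)
        by_key = {(s.subject_id, s.label, s.segment_index): s for s in segs}
        for s in loaded:
            np.testing.assert_allclose(
                s.samples, by_key[(s.subject_id, s.label, s.segment_index)].samples)


def test_default_taxonomy_has_15_unique_classes():
    assert DEFAULT_TAXONOMY.n_classes == 15
    assert len(set(DEFAULT_TAXONOMY.abbreviations)) == 15
    assert DEFAULT_TAXONOMY.abbreviations[0] == "UPS"
    assert DEFAULT_TAXONOMY.abbreviations[-1] == "FOB"
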