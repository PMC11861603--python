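import numpy as np
import pytest

from harfusion.signal_core import AccelSegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_segment(rng):
    """Factory for random full-size (2500, 3) segments in raw-count scale."""

    def factory(scale: float = 500.0, fs: float = 250.0, n: int = 2500,
                subject_id: str = "S000", label: str = "WK", offset: float = 0.0):
        samples = rng.normal(offset, scale, size=(n, 3))
        return AccelSegment(samples=samples, fs=fs, subject_id=subject_id, label=label)

    return factory


@pytest.fixture
def tiny_segments(rng):
    """Small multi-subject dataset of 5-sample segments for split logic tests."""

    def factory(n_subjects: int = 12, per_subject: int = 4, n_classes: int = 2):
        segs = []
        for s in range(n_subjects):
            for i in range(per_subject):
                segs.append(AccelSegment(
                    samples=rng.normal(0, 1, size=(5, 3)), fs=5.0,
                    subject_id=f"S{s:03d}", label=f"C{i % n_classes}",
                    segment_index=i))
        return segs

    return factory
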