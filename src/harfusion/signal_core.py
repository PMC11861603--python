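"""Core domain types and raw-signal operations.

The unit of classification is a fixed-length tri-axial accelerometer window
(:class:`AccelSegment`): 10 s at 250 Hz by default, i.e. 2500 samples x 3
axes, in dimensionless raw sensor counts.  Raw streams are segmented without
any filtering or normalisation; evaluation splits are drawn at the subject
level so no person contributes to both training and test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import io
import zipfile

import numpy as np
import pandas as pd

__all__ = [
    "HarfusionError",
    "NonFiniteSignalError",
    "InsufficientSubjectsError",
    "NegativeSigmaError",
    "EmptyDatasetError",
    "AccelSegment",
    "ActivityTaxonomy",
    "DEFAULT_TAXONOMY",
    "DatasetSplit",
    "segment_signal",
    "split_by_subject",
    "add_gaussian_noise",
    "dataset_sigma",
    "PAPER_NOISE_SIGMAS",
    "save_segments_npz",
    "load_segments_npz",
    "segments_to_frame",
    "frame_to_segments",
    "savez_deterministic",
]

#: Noise-sweep standard deviations in raw counts: 5/10/20/30/40/50 % of a
#: pooled signal sigma of 550.94 (the 5 % entry is conventionally 22.5).
PAPER_NOISE_SIGMAS = (22.5, 55.0, 110.0, 165.0, 220.0, 275.0)

#: Fixed column order of the long-format CSV interchange format.
CSV_COLUMNS = ("subject_id", "label", "segment_index", "sample_index", "ax", "ay", "az")


class HarfusionError(Exception):
    """Base class for all package errors."""


class NonFiniteSignalError(HarfusionError, ValueError):
    """Raw signal contains NaN or infinite values."""


class InsufficientSubjectsError(HarfusionError, ValueError):
    """Too few distinct subjects to form the requested partitions."""


class NegativeSigmaError(HarfusionError, ValueError):
    """Gaussian noise level must be non-negative."""


class EmptyDatasetError(HarfusionError, ValueError):
    """An operation that needs at least one segment received none."""


@dataclass
class AccelSegment:
    """One fixed-length tri-axial accelerometer window.

    Parameters
    ----------
    samples : ndarray of shape (n_samples, 3)
        Acceleration in raw sensor counts, axis order (x, y, z).
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Opaque subject identifier (drives subject-independent splitting).
    label : str
        Activity class identifier.
    segment_index : int
        Ordinal of this window within its subject/activity recording.
    """

    samples: np.ndarray
    fs: float = 250.0
    subject_id: str = "S000"
    label: str = ""
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise NonFiniteSignalError("segment contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ActivityTaxonomy:
    """Ordered activity classes as (full name, abbreviation) pairs."""

    classes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        abbrevs = [a for _, a in self.classes]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("class abbreviations must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(a for _, a in self.classes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.classes)


#: The 15-activity taxonomy: nine daily activities plus six fall types.
DEFAULT_TAXONOMY = ActivityTaxonomy(
    classes=(
        ("Going upstairs", "UPS"),
        ("Going downstairs", "DWS"),
        ("Sitting on a chair", "SC"),
        ("Getting up from a chair", "GC"),
        ("Lying up on the bed", "LUB"),
        ("Lying down on the bed", "LDB"),
        ("Walking", "WK"),
        ("Squat and rise", "SQ"),
        ("Jump rope", "JR"),
        ("Fall forward", "FF"),
        ("Fall forward on one's knees", "FFK"),
        ("Fall back", "FB"),
        ("Look to the left and fall", "LF"),
        ("Look to the right and fall", "RF"),
        ("Fall out of the bed", "FOB"),
    )
)


@dataclass
class DatasetSplit:
    """Subject-independent train/validation/test partition of segments."""

    train: list[AccelSegment]
    validation: list[AccelSegment]
    test: list[AccelSegment]
    split_seed: int = 0

    def subjects(self, part: str) -> set[str]:
        return {s.subject_id for s in getattr(self, part)}

    def __post_init__(self) -> None:
        trainval = self.subjects("train") | self.subjects("validation")
        if trainval & self.subjects("test"):
            raise ValueError("test subjects overlap train/validation subjects")


def segment_signal(stream: np.ndarray, fs: float, segment_seconds: float,
                   subject_id: str = "S000", label: str = "") -> list[AccelSegment]:
    """Cut a raw (N, 3) stream into consecutive non-overlapping windows.

    The raw data are segmented directly — no filtering, resampling or
    normalisation.  A trailing remainder shorter than one window is dropped.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if segment_seconds <= 0:
        raise ValueError("segment_seconds must be positive")
    stream = np.asarray(stream, dtype=np.float64)
    if stream.ndim != 2 or stream.shape[1] != 3:
        raise ValueError(f"stream must have shape (N, 3), got {stream.shape}")
    if not np.all(np.isfinite(stream)):
        raise NonFiniteSignalError("stream contains non-finite values")
    length = int(round(fs * segment_seconds))
    n_segments = stream.shape[0] // length
    return [
        AccelSegment(
            samples=stream[i * length:(i + 1) * length].copy(),
            fs=fs,
            subject_id=subject_id,
            label=label,
            segment_index=i,
        )
        for i in range(n_segments)
    ]


def split_by_subject(segments: list[AccelSegment], test_fraction: float = 0.2,
                     val_fraction: float = 0.2, seed: int = 0) -> DatasetSplit:
    """Randomly partition *subjects* (not segments) into train/val/test.

    Fractions apply to subject counts, rounded to the nearest integer (at
    least one subject per requested non-empty partition).  Deterministic for
    a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must lie in [0, 1)")
    subjects = sorted({s.subject_id for s in segments})
    n_parts = 3 if val_fraction > 0 else 2
    if len(subjects) < max(3, n_parts):
        raise InsufficientSubjectsError(
            f"need at least 3 distinct subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_test = max(1, int(round(test_fraction * len(subjects))))
    n_val = int(round(val_fraction * len(subjects)))
    if val_fraction > 0:
        n_val = max(1, n_val)
    if n_test + n_val >= len(subjects):
        raise InsufficientSubjectsError(
            "not enough subjects for the requested test/validation fractions")
    test_set = {subjects[i] for i in order[:n_test]}
    val_set = {subjects[i] for i in order[n_test:n_test + n_val]}
    split = DatasetSplit(
        train=[s for s in segments if s.subject_id not in test_set | val_set],
        validation=[s for s in segments if s.subject_id in val_set],
        test=[s for s in segments if s.subject_id in test_set],
        split_seed=seed,
    )
    return split


def add_gaussian_noise(segment: AccelSegment, sigma: float, seed: int = 0) -> AccelSegment:
    """Return a copy with i.i.d. zero-mean Gaussian noise added to every value."""
    if sigma < 0:
        raise NegativeSigmaError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    noisy = segment.samples + rng.normal(0.0, sigma, size=segment.samples.shape)
    return replace(segment, samples=noisy)


def dataset_sigma(segments: list[AccelSegment]) -> float:
    """Pooled standard deviation over all values of all axes of all segments.

    Used to express noise levels as percentages of the signal scale.
    """
    if not segments:
        raise EmptyDatasetError("dataset_sigma needs at least one segment")
    pooled = np.concatenate([s.samples.ravel() for s in segments])
    return float(np.std(pooled))


# ---------------------------------------------------------------------------
# storage

def savez_deterministic(path, **arrays) -> None:
    """np.savez with a fixed zip timestamp, so identical arrays give identical bytes."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def save_segments_npz(path, segments: list[AccelSegment]) -> None:
    """Store equally sized segments as one NPZ archive (one array per field)."""
    if not segments:
        raise EmptyDatasetError("cannot save an empty segment list")
    lengths = {s.n_samples for s in segments}
    if len(lengths) != 1:
        raise ValueError("all segments must have the same length")
    savez_deterministic(
        path,
        samples=np.stack([s.samples for s in segments]),
        fs=np.array([segments[0].fs]),
        subject_id=np.array([s.subject_id for s in segments], dtype=str),
        label=np.array([s.label for s in segments], dtype=str),
        segment_index=np.array([s.segment_index for s in segments], dtype=np.int64),
    )


def load_segments_npz(path) -> list[AccelSegment]:
    with np.load(path, allow_pickle=False) as data:
        fs = float(data["fs"][0])
        return [
            AccelSegment(
                samples=data["samples"][i],
                fs=fs,
                subject_id=str(data["subject_id"][i]),
                label=str(data["label"][i]),
                segment_index=int(data["segment_index"][i]),
            )
            for i in range(data["samples"].shape[0])
        ]


def segments_to_frame(segments: list[AccelSegment]) -> pd.DataFrame:
    """Long-format table with columns subject_id, label, segment_index,
    sample_index, ax, ay, az."""
    if not segments:
        raise EmptyDatasetError("cannot export an empty segment list")
    frames = []
    for s in segments:
        frames.append(pd.DataFrame({
            "subject_id": s.subject_id,
            "label": s.label,
            "segment_index": s.segment_index,
            "sample_index": np.arange(s.n_samples),
            "ax": s.samples[:, 0],
            "ay": s.samples[:, 1],
            "az": s.samples[:, 2],
        }))
    return pd.concat(frames, ignore_index=True)[list(CSV_COLUMNS)]


def frame_to_segments(df: pd.DataFrame, fs: float = 250.0) -> list[AccelSegment]:
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    segments = []
    for (subj, label, idx), grp in df.groupby(
            ["subject_id", "label", "segment_index"], sort=True):
        grp = grp.sort_values("sample_index")
        segments.append(AccelSegment(
            samples=grp[["ax", "ay", "az"]].to_numpy(),
            fs=fs, subject_id=str(subj), label=str(label), segment_index=int(idx),
        ))
    return segments
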