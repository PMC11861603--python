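"""Time-series-to-image encodings of accelerometer windows.

Three transforms each map one :class:`~harfusion.signal_core.AccelSegment`
to a 64x64x3 8-bit image:

* **Spectrogram** — squared STFT magnitude per axis, decibel-scaled, the
  three axes stacked horizontally, jointly min-max normalised and mapped
  through a perceptual colormap.
* **Modified recurrence plot (RP)** — the unthresholded pairwise-distance
  matrix |v_i - v_j| per axis (the classical Heaviside binarisation is
  deliberately omitted to keep the full distance structure); the x/y/z axes
  become the R/G/B channels.
* **Modified multi-channel plot (MP)** — every raw value is min-max scaled
  into [0, 255] and its integer part, first-second decimals and third-fourth
  decimals become the R, G and B components of one pixel; each axis fills a
  50x50 tile and the tiles are stacked vertically.

All transforms are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from PIL import Image
from scipy.signal import get_window

from .signal_core import AccelSegment, HarfusionError

__all__ = [
    "IMAGE_SIZE",
    "RECON_METHODS",
    "SeriesTooShortError",
    "ReconImage",
    "SpectrogramConfig",
    "RPConfig",
    "stft_magnitude",
    "spectrogram_matrix",
    "spectrogram_image",
    "block_average",
    "rp_matrix",
    "rp_image",
    "mp_scale",
    "mp_encode",
    "mp_image",
    "reconstruct_all",
    "SpectrogramImager",
    "RecurrencePlotImager",
    "MultiChannelPlotImager",
    "save_png",
    "load_png",
    "save_images_npz",
]

IMAGE_SIZE = 64
RECON_METHODS = ("spectrogram", "rp", "mp")

#: Window lengths (seconds) supported by the spectrogram sweep.
SPECTROGRAM_WINDOW_CHOICES = (1, 2, 5, 10)


class SeriesTooShortError(HarfusionError, ValueError):
    """The series is shorter than one STFT window."""


@dataclass
class ReconImage:
    """A 64x64x3 8-bit image produced by one reconstruction method."""

    pixels: np.ndarray
    method: str
    source: tuple[str, str, int] = ("", "", 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"pixels must be {IMAGE_SIZE}x{IMAGE_SIZE}x3, "
                             f"got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")
        if self.method not in RECON_METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT parameters.

    window_seconds=10 with 50 % overlap is the default operating point; on a
    10 s segment this yields a single frame per axis.
    """

    window_seconds: float = 10.0
    overlap_fraction: float = 0.5
    log_scale: bool = True
    colormap: str = "viridis"
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")


@dataclass(frozen=True)
class RPConfig:
    """Recurrence-plot parameters.

    The 2500-point series is block-averaged down to ``downsample_length``
    points before the O(n^2) distance matrix, an approximation of computing
    the full-resolution plot and resizing it.
    """

    downsample_length: int = 256

    def __post_init__(self) -> None:
        if self.downsample_length < 2:
            raise ValueError("downsample_length must be >= 2")


@lru_cache(maxsize=8)
def _colormap_lut(name: str) -> np.ndarray:
    """256-entry RGB lookup table in [0, 255] floats."""
    if name in ("gray", "grey", "grayscale"):
        ramp = np.linspace(0.0, 255.0, 256)
        return np.stack([ramp, ramp, ramp], axis=1)
    import matplotlib

    cmap = matplotlib.colormaps[name].resampled(256)
    return cmap(np.linspace(0.0, 1.0, 256))[:, :3] * 255.0


def _resize_bilinear(arr: np.ndarray, size: int = IMAGE_SIZE) -> np.ndarray:
    """Bilinear resize of an (H, W) or (H, W, 3) float array to size x size."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 2:
        img = Image.fromarray(arr, mode="F").resize((size, size), Image.BILINEAR)
        return np.asarray(img, dtype=np.float64)
    chans = [
        np.asarray(
            Image.fromarray(arr[:, :, c], mode="F").resize((size, size), Image.BILINEAR),
            dtype=np.float64)
        for c in range(arr.shape[2])
    ]
    return np.stack(chans, axis=2)


def _quantize(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def _minmax01(arr: np.ndarray) -> np.ndarray:
    """Joint min-max to [0, 1]; a constant array maps to all zeros."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# spectrogram

def stft_magnitude(series: np.ndarray, fs: float, cfg: SpectrogramConfig) -> np.ndarray:
    """Squared one-sided STFT magnitude |X(m, w)|^2.

    Frames start at multiples of the hop H = round(L * (1 - overlap)); no
    padding or centring, so n_frames = floor((N - L) / H) + 1 and the
    frequency axis has floor(L / 2) + 1 bins.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[0]
    length = int(round(cfg.window_seconds * fs))
    if n < length:
        raise SeriesTooShortError(
            f"series of {n} samples is shorter than one window of {length}")
    hop = max(1, int(round(length * (1.0 - cfg.overlap_fraction))))
    n_frames = (n - length) // hop + 1
    win = (np.ones(length) if cfg.window in ("rectangular", "boxcar")
           else get_window(cfg.window, length))
    starts = np.arange(n_frames) * hop
    frames = series[starts[:, None] + np.arange(length)] * win
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    return spec.T  # (n_freq_bins, n_frames)


def spectrogram_matrix(segment: AccelSegment, cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """Decibel-scaled spectrograms of the three axes stacked horizontally.

    Rows are frequency bins; columns are frame index within axis, axes in
    x, y, z order, so the width is 3 * n_frames.
    """
    cfg = cfg or SpectrogramConfig()
    mats = []
    for axis in range(3):
        spec = stft_magnitude(segment.samples[:, axis], segment.fs, cfg)
        if cfg.log_scale:
            spec = 10.0 * np.log10(np.clip(spec, 1e-12, None))
        mats.append(spec)
    return np.hstack(mats)


def spectrogram_image(segment: AccelSegment, cfg: SpectrogramConfig | None = None) -> ReconImage:
    """Stacked tri-axial spectrogram rendered through the colormap at 64x64."""
    cfg = cfg or SpectrogramConfig()
    stacked = _minmax01(spectrogram_matrix(segment, cfg))
    lut = _colormap_lut(cfg.colormap)
    rgb = lut[np.rint(stacked * 255).astype(np.intp)]
    resized = _resize_bilinear(rgb)
    return ReconImage(_quantize(resized), "spectrogram",
                      (segment.subject_id, segment.label, segment.segment_index))


# ---------------------------------------------------------------------------
# modified recurrence plot

def block_average(series: np.ndarray, target_len: int) -> np.ndarray:
    """Downsample by averaging over ~equal consecutive blocks."""
    series = np.asarray(series, dtype=np.float64)
    if series.shape[0] <= target_len:
        return series.copy()
    return np.array([b.mean() for b in np.array_split(series, target_len)])


def rp_matrix(series: np.ndarray, cfg: RPConfig | None = None) -> np.ndarray:
    """Unthresholded recurrence matrix D_ij = |v_i - v_j| of one axis.

    Scalar absolute difference (embedding dimension 1); no Heaviside
    binarisation is applied.
    """
    cfg = cfg or RPConfig()
    v = block_average(series, cfg.downsample_length)
    return np.abs(v[:, None] - v[None, :])


def rp_image(segment: AccelSegment, cfg: RPConfig | None = None) -> ReconImage:
    """Per-axis recurrence matrices as R(x), G(y), B(z) channels at 64x64."""
    cfg = cfg or RPConfig()
    channels = []
    for axis in range(3):
        d = rp_matrix(segment.samples[:, axis], cfg)
        channels.append(_minmax01(d) * 255.0)
    resized = _resize_bilinear(np.stack(channels, axis=2))
    return ReconImage(_quantize(resized), "rp",
                      (segment.subject_id, segment.label, segment.segment_index))


# ---------------------------------------------------------------------------
# modified multi-channel plot

def mp_scale(samples: np.ndarray) -> np.ndarray:
    """Min-max scale all values jointly onto the real interval [0, 255].

    A constant input (max == min) scales to all zeros.
    """
    samples = np.asarray(samples, dtype=np.float64)
    return _minmax01(samples) * 255.0


def mp_encode(scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Digit decomposition of scaled values into (R, G, B) integer channels.

    R is the integer part, G the first-second decimal places, B the
    third-fourth decimal places, by truncation on the 1e-4 tick grid (a 1e-8
    guard absorbs float representation error, e.g. 123.4567 -> (123, 45, 67)).
    The identity R + G/100 + B/1e4 reconstructs the value to within 1e-4.
    """
    scaled = np.asarray(scaled, dtype=np.float64)
    if scaled.min() < 0 or scaled.max() > 255:
        raise ValueError("scaled values must lie in [0, 255]")
    q = np.floor(scaled * 1e4 + 1e-8).astype(np.int64)
    return q // 10000, (q // 100) % 100, q % 100


def mp_image(segment: AccelSegment) -> ReconImage:
    """Digit-decomposed RGB encoding with the three axes as stacked tiles.

    Each axis's values fill a square tile row-major; the x, y, z tiles are
    stacked vertically and the result resized to 64x64.
    """
    scaled = mp_scale(segment.samples)
    side = int(np.ceil(np.sqrt(segment.n_samples)))
    tiles = []
    for axis in range(3):
        r, g, b = mp_encode(scaled[:, axis])
        tile = np.zeros((side * side, 3), dtype=np.float64)
        tile[:segment.n_samples, 0] = r
        tile[:segment.n_samples, 1] = g
        tile[:segment.n_samples, 2] = b
        tiles.append(tile.reshape(side, side, 3))
    stacked = np.concatenate(tiles, axis=0)  # (3*side, side, 3)
    resized = _resize_bilinear(stacked)
    return ReconImage(_quantize(resized), "mp",
                      (segment.subject_id, segment.label, segment.segment_index))


# ---------------------------------------------------------------------------
# batch interface

def reconstruct_all(segment: AccelSegment, spec_cfg: SpectrogramConfig | None = None,
                    rp_cfg: RPConfig | None = None) -> tuple[ReconImage, ReconImage, ReconImage]:
    """All three encodings in fixed (spectrogram, rp, mp) order."""
    return (
        spectrogram_image(segment, spec_cfg),
        rp_image(segment, rp_cfg),
        mp_image(segment),
    )


class _BaseImager:
    """sklearn-style stateless transformer over lists of segments."""

    def fit(self, X, y=None):
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {k: v for k, v in vars(self).items() if not k.endswith("_")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class SpectrogramImager(_BaseImager):
    """Transform segments into stacked tri-axial spectrogram images."""

    def __init__(self, window_seconds: float = 10.0, overlap_fraction: float = 0.5,
                 log_scale: bool = True, colormap: str = "viridis",
                 window: str = "hann") -> None:
        self.window_seconds = window_seconds
        self.overlap_fraction = overlap_fraction
        self.log_scale = log_scale
        self.colormap = colormap
        self.window = window

    def transform(self, X: list[AccelSegment]) -> np.ndarray:
        cfg = SpectrogramConfig(self.window_seconds, self.overlap_fraction,
                                self.log_scale, self.colormap, self.window)
        return np.stack([spectrogram_image(s, cfg).pixels for s in X])


class RecurrencePlotImager(_BaseImager):
    """Transform segments into unthresholded recurrence-plot RGB images."""

    def __init__(self, downsample_length: int = 256) -> None:
        self.downsample_length = downsample_length

    def transform(self, X: list[AccelSegment]) -> np.ndarray:
        cfg = RPConfig(self.downsample_length)
        return np.stack([rp_image(s, cfg).pixels for s in X])


class MultiChannelPlotImager(_BaseImager):
    """Transform segments into digit-decomposed multi-channel plot images."""

    def transform(self, X: list[AccelSegment]) -> np.ndarray:
        return np.stack([mp_image(s).pixels for s in X])


# ---------------------------------------------------------------------------
# storage

def save_png(path, image: ReconImage) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")


def load_png(path, method: str = "spectrogram") -> ReconImage:
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return ReconImage(pixels, method)


def save_images_npz(path, images: np.ndarray, labels: np.ndarray,
                    subjects: np.ndarray, method: str = "") -> None:
    """NPZ batch format: uint8 image tensor plus aligned label/subject arrays."""
    from .signal_core import savez_deterministic

    savez_deterministic(
        path,
        images=np.asarray(images, dtype=np.uint8),
        labels=np.asarray(labels, dtype=str),
        subjects=np.asarray(subjects, dtype=str),
        method=np.array([method], dtype=str),
    )
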