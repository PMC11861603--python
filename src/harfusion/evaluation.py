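"""Metric suite and experiment harnesses.

Metrics: top-1 and top-3 accuracy, macro one-vs-rest precision and recall
(accuracy = TP+TN over all from the multiclass confusion, i.e. trace/total),
macro one-vs-rest ROC AUC, and the full confusion matrix.  Macro averaging
is the natural choice for the balanced class design.

Harnesses mirror the study protocols: a spectrogram window-size sweep
(1/2/5/10 s, half-window overlap), a reconstruction-method comparison
(1-D raw baseline, each single encoding, and the three-branch fusion, all on
one subject-independent split), and a Gaussian-noise robustness sweep where
noise is added to the raw *test* signals only and images are re-encoded.
Replicates re-seed training only; the subject split is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_score, recall_score, roc_auc_score

from .signal_core import (AccelSegment, DatasetSplit, HarfusionError,
                          add_gaussian_noise, dataset_sigma, split_by_subject)
from .reconstruction import (RECON_METHODS, RPConfig, SpectrogramConfig,
                             MultiChannelPlotImager, RecurrencePlotImager,
                             SpectrogramImager)
from .fusion_model import Baseline1DClassifier, FusionImageClassifier, top_k_labels

__all__ = [
    "MetricsReport",
    "SweepResult",
    "TrainedCondition",
    "ComparisonResult",
    "binary_metrics",
    "compute_metrics",
    "window_size_sweep",
    "method_comparison",
    "noise_sweep",
    "encode_split",
]

METRIC_FIELDS = ("top1_accuracy", "top3_accuracy", "precision", "recall", "roc_auc")


class DegenerateLabelsError(HarfusionError, ValueError):
    """ROC AUC is undefined when the truth contains a single class."""


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, precision and recall from binary confusion counts."""
    return {
        "accuracy": (tp + tn) / (tp + fp + tn + fn),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
    }


@dataclass
class MetricsReport:
    """Evaluation metrics of one run; all metric values lie in [0, 1]."""

    top1_accuracy: float
    top3_accuracy: float
    precision: float
    recall: float
    roc_auc: float
    confusion: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if int(self.confusion.sum()) != self.n_samples:
            raise ValueError("confusion entries must sum to n_samples")
        if self.top3_accuracy < self.top1_accuracy - 1e-12:
            raise ValueError("top-3 accuracy cannot be below top-1")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_FIELDS}


def compute_metrics(true_labels: np.ndarray, probability_matrix: np.ndarray) -> MetricsReport:
    """Score class-probability predictions against integer true labels.

    ``true_labels`` are indices into the columns of ``probability_matrix``.
    Precision/recall are per-class one-vs-rest, macro-averaged; ROC AUC is
    macro one-vs-rest over the probability scores (classes without both a
    positive and a negative example are skipped).
    """
    y = np.asarray(true_labels)
    probs = np.asarray(probability_matrix, dtype=np.float64)
    if probs.ndim != 2 or y.shape[0] != probs.shape[0]:
        raise ValueError("true_labels and probability_matrix lengths differ")
    n, n_classes = probs.shape
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError("labels outside the probability matrix columns")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-4:
        raise ValueError("probability rows must sum to 1 within 1e-4")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("ROC AUC needs at least two classes in truth")

    labels = np.arange(n_classes)
    pred = probs.argmax(axis=1)
    topk = top_k_labels(probs, 3)
    aucs = []
    for c in labels:
        pos = y == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, probs[:, c]))
    return MetricsReport(
        top1_accuracy=float((pred == y).mean()),
        top3_accuracy=float((topk == y[:, None]).any(axis=1).mean()),
        precision=float(precision_score(y, pred, labels=labels, average="macro",
                                        zero_division=0)),
        recall=float(recall_score(y, pred, labels=labels, average="macro",
                                  zero_division=0)),
        roc_auc=float(np.mean(aucs)),
        confusion=confusion_matrix(y, pred, labels=labels),
        n_samples=n,
    )


def save_confusion_heatmap(confusion: np.ndarray, path,
                           class_names: list[str] | None = None) -> None:
    """Render a confusion matrix as a PNG heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    confusion = np.asarray(confusion)
    n = confusion.shape[0]
    names = class_names or [str(i) for i in range(n)]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * n), max(4, 0.5 * n)))
    im = ax.imshow(confusion, cmap="Blues")
    ax.set_xticks(range(n), names, rotation=90)
    ax.set_yticks(range(n), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(confusion[i, j]), ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


@dataclass
class SweepResult:
    """Per-condition replicate metrics with mean (sd) aggregation."""

    runs: dict[str, list[MetricsReport]] = field(default_factory=dict)

    def add(self, condition: str, report: MetricsReport) -> None:
        self.runs.setdefault(condition, []).append(report)

    @property
    def n_runs(self) -> int:
        return sum(len(v) for v in self.runs.values())

    def aggregate(self) -> pd.DataFrame:
        """One row per condition; `<metric>_mean` and `<metric>_sd` columns."""
        rows = []
        for condition, reports in self.runs.items():
            if not reports:
                raise ValueError(f"condition {condition!r} has no replicates")
            row: dict = {"condition": condition, "replicates": len(reports)}
            for m in METRIC_FIELDS:
                vals = np.array([getattr(r, m) for r in reports])
                row[f"{m}_mean"] = float(vals.mean())
                row[f"{m}_sd"] = float(vals.std(ddof=0))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.aggregate().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# encoding helpers

def _imagers(spec_cfg: SpectrogramConfig, rp_cfg: RPConfig) -> dict:
    return {
        "spectrogram": SpectrogramImager(
            window_seconds=spec_cfg.window_seconds,
            overlap_fraction=spec_cfg.overlap_fraction,
            log_scale=spec_cfg.log_scale, colormap=spec_cfg.colormap,
            window=spec_cfg.window),
        "rp": RecurrencePlotImager(downsample_length=rp_cfg.downsample_length),
        "mp": MultiChannelPlotImager(),
    }


def encode_split(segments: list[AccelSegment],
                 spec_cfg: SpectrogramConfig | None = None,
                 rp_cfg: RPConfig | None = None,
                 methods: tuple[str, ...] = RECON_METHODS) -> dict[str, np.ndarray]:
    """Encode segments with each requested method -> (n, 64, 64, 3) uint8."""
    imagers = _imagers(spec_cfg or SpectrogramConfig(), rp_cfg or RPConfig())
    return {m: imagers[m].transform(segments) for m in methods}


def _labels(segments: list[AccelSegment]) -> np.ndarray:
    return np.array([s.label for s in segments])


def _raw(segments: list[AccelSegment]) -> np.ndarray:
    return np.stack([s.samples for s in segments]).astype(np.float32)


def _triple(images: dict[str, np.ndarray], methods: tuple[str, ...]) -> np.ndarray:
    return np.stack([images[m] for m in methods], axis=1)


def _class_indices(classes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, labels)
    if not np.array_equal(classes[idx], labels):
        raise ValueError("labels outside the model's taxonomy")
    return idx


def _evaluate(model, X, labels: np.ndarray) -> MetricsReport:
    probs = model.predict_proba(X)
    return compute_metrics(_class_indices(model.classes_, labels), probs)


# ---------------------------------------------------------------------------
# harnesses

def window_size_sweep(segments: list[AccelSegment], sizes=(1, 2, 5, 10),
                      replicates: int = 4, base_seed: int = 0, epochs: int = 10,
                      test_fraction: float = 0.2, val_fraction: float = 0.2,
                      colormap: str = "viridis", **clf_kwargs) -> SweepResult:
    """Train a single-branch spectrogram model per window size per replicate.

    Replicate r uses seed base_seed + r; the subject split (seed base_seed)
    is shared by every condition.
    """
    split = split_by_subject(segments, test_fraction, val_fraction, seed=base_seed)
    result = SweepResult()
    for size in sizes:
        cfg = SpectrogramConfig(window_seconds=size, colormap=colormap)
        imager = SpectrogramImager(window_seconds=size, colormap=colormap)
        xs = {part: imager.transform(getattr(split, part))[:, None]
              for part in ("train", "validation", "test")}
        for r in range(replicates):
            clf = FusionImageClassifier(n_branches=1, epochs=epochs,
                                        seed=base_seed + r, **clf_kwargs)
            clf.fit(xs["train"], _labels(split.train),
                    validation_data=(xs["validation"], _labels(split.validation)))
            result.add(f"window={size}s", _evaluate(clf, xs["test"], _labels(split.test)))
    return result


@dataclass
class TrainedCondition:
    """Replicate models of one comparison condition plus their input kind."""

    name: str
    input_kind: str  # 'raw', one reconstruction method, or 'triple'
    models: list = field(default_factory=list)


@dataclass
class ComparisonResult:
    sweep: SweepResult
    conditions: dict[str, TrainedCondition]
    split: DatasetSplit
    spec_cfg: SpectrogramConfig
    rp_cfg: RPConfig


def method_comparison(segments: list[AccelSegment], replicates: int = 4,
                      base_seed: int = 0, epochs: int = 10,
                      test_fraction: float = 0.2, val_fraction: float = 0.2,
                      spec_cfg: SpectrogramConfig | None = None,
                      rp_cfg: RPConfig | None = None,
                      conditions: tuple[str, ...] = ("1d_baseline", "spectrogram",
                                                     "rp", "mp", "fusion"),
                      **clf_kwargs) -> ComparisonResult:
    """Evaluate the 1-D baseline, each single encoding and the fusion model.

    All conditions share the identical subject partition (seed base_seed);
    replicate r trains with seed base_seed + r.
    """
    spec_cfg = spec_cfg or SpectrogramConfig()
    rp_cfg = rp_cfg or RPConfig()
    split = split_by_subject(segments, test_fraction, val_fraction, seed=base_seed)
    parts = {p: getattr(split, p) for p in ("train", "validation", "test")}
    labels = {p: _labels(v) for p, v in parts.items()}
    images = {p: encode_split(v, spec_cfg, rp_cfg) for p, v in parts.items()}
    raw = {p: _raw(v) for p, v in parts.items()}
    seg_len = raw["train"].shape[1]

    result = SweepResult()
    trained: dict[str, TrainedCondition] = {}
    for name in conditions:
        kind = ("raw" if name == "1d_baseline"
                else "triple" if name == "fusion" else name)
        cond = TrainedCondition(name=name, input_kind=kind)
        for r in range(replicates):
            seed = base_seed + r
            if kind == "raw":
                clf = Baseline1DClassifier(segment_length=seg_len, epochs=epochs,
                                           seed=seed, **clf_kwargs)
                data = raw
            elif kind == "triple":
                clf = FusionImageClassifier(n_branches=3, epochs=epochs,
                                            seed=seed, **clf_kwargs)
                data = {p: _triple(images[p], RECON_METHODS) for p in parts}
            else:
                clf = FusionImageClassifier(n_branches=1, epochs=epochs,
                                            seed=seed, **clf_kwargs)
                data = {p: images[p][kind][:, None] for p in parts}
            clf.fit(data["train"], labels["train"],
                    validation_data=(data["validation"], labels["validation"]))
            cond.models.append(clf)
            result.add(name, _evaluate(clf, data["test"], labels["test"]))
        trained[name] = cond
    return ComparisonResult(result, trained, split, spec_cfg, rp_cfg)


@dataclass
class NoiseSweepResult:
    sweep: SweepResult
    degradation: pd.DataFrame  # columns: model, sigma, top1_mean, degradation_mean


def noise_sweep(trained: dict[str, TrainedCondition],
                test_segments: list[AccelSegment], sigmas, seed: int = 0,
                spec_cfg: SpectrogramConfig | None = None,
                rp_cfg: RPConfig | None = None) -> NoiseSweepResult:
    """Perturb the raw test signals, re-encode, and re-score trained models.

    sigma = 0 reproduces the clean evaluation exactly.  Degradation is the
    clean top-1 minus the noisy top-1, per model, per sigma.
    """
    spec_cfg = spec_cfg or SpectrogramConfig()
    rp_cfg = rp_cfg or RPConfig()
    result = SweepResult()
    clean_top1: dict[str, float] = {}
    rows = []
    for sigma in sigmas:
        noisy = [add_gaussian_noise(s, sigma, seed=seed + 7919 * i)
                 for i, s in enumerate(test_segments)]
        labels = _labels(noisy)
        needed = {c.input_kind for c in trained.values()}
        images = (encode_split(noisy, spec_cfg, rp_cfg,
                               tuple(m for m in RECON_METHODS
                                     if m in needed or "triple" in needed))
                  if needed - {"raw"} else {})
        raw = _raw(noisy) if "raw" in needed else None
        for name, cond in trained.items():
            if cond.input_kind == "raw":
                X = raw
            elif cond.input_kind == "triple":
                X = _triple(images, RECON_METHODS)
            else:
                X = images[cond.input_kind][:, None]
            top1s = []
            for model in cond.models:
                report = _evaluate(model, X, labels)
                result.add(f"{name}|sigma={sigma:g}", report)
                top1s.append(report.top1_accuracy)
            mean_top1 = float(np.mean(top1s))
            if sigma == 0:
                clean_top1[name] = mean_top1
            rows.append({"model": name, "sigma": float(sigma),
                         "top1_mean": mean_top1})
    frame = pd.DataFrame(rows)
    # degradation relative to the sigma=0 row when present, else to the
    # smallest sigma evaluated
    ref = {m: clean_top1.get(m, frame[frame["model"] == m]
                             .sort_values("sigma")["top1_mean"].iloc[0])
           for m in frame["model"].unique()}
    frame["degradation_mean"] = frame.apply(
        lambda r: ref[r["model"]] - r["top1_mean"], axis=1)
    return NoiseSweepResult(result, frame)
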