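"""Pixel-level scoring: per-class Jaccard, confusion matrices and the
achievable segmentation accuracy (ASA).

Predicted superpixel labels are projected to pixels (every pixel
inherits its superpixel's label); scoring then excludes ground-truth
background and ignore pixels.  Per class k,

    J_k = tp_k / (tp_k + fp_k + fn_k) * 100

and the class-average is the unweighted mean over the four organ
classes, so the heavy class skew does not mask failures on small
organs.  ASA is the upper bound the oversegmentation imposes: each
superpixel takes the ground-truth label with the largest intersection,
and ASA is the resulting pixel accuracy (1 = perfect boundary
adherence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import BACKGROUND, FOREGROUND_CLASSES, LabelImage
from .overseg import Oversegmentation

_N = len(FOREGROUND_CLASSES)


@dataclass
class MetricsReport:
    """Confusion counts and derived scores over evaluated pixels."""

    confusion: np.ndarray                 # 4 x 4, rows = true, cols = pred
    per_class_jaccard: dict               # class code -> % (NaN if no support)
    class_average_jaccard: float          # % over classes with support
    asa: Optional[float] = None
    achievable_jaccard: Optional[dict] = None
    unsupported_classes: list = field(default_factory=list)
    n_evaluated: Optional[int] = None     # incl. pixels predicted invalid

    @property
    def pixel_accuracy(self) -> float:
        total = self.n_evaluated or self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else 0.0

    def normalized_confusion(self) -> np.ndarray:
        return normalize_confusion(self.confusion)

    def to_dict(self) -> dict:
        from .data_model import CLASS_NAMES
        return {
            "per_class_jaccard": {CLASS_NAMES[c]: v for c, v in
                                  self.per_class_jaccard.items()},
            "class_average_jaccard": self.class_average_jaccard,
            "pixel_accuracy": self.pixel_accuracy,
            "asa": self.asa,
            "achievable_jaccard": ({CLASS_NAMES[c]: v for c, v in
                                    self.achievable_jaccard.items()}
                                   if self.achievable_jaccard else None),
            "confusion": self.confusion.tolist(),
        }


def project_to_pixels(overseg: Oversegmentation,
                      superpixel_labels: np.ndarray) -> LabelImage:
    """Pixel label = its superpixel's label; unclustered pixels get the
    background code."""
    labels = np.asarray(superpixel_labels)
    if len(labels) < overseg.n_segments:
        raise ValueError(
            f"labels cover {len(labels)} ids, oversegmentation has "
            f"{overseg.n_segments}")
    out = np.full(overseg.ids.shape, BACKGROUND, dtype=np.uint8)
    valid = overseg.ids >= 0
    out[valid] = labels[overseg.ids[valid]]
    return LabelImage(out)


def confusion_counts(pred: LabelImage, gt: LabelImage) -> np.ndarray:
    """4x4 confusion over pixels whose ground truth is an organ class.

    Ground-truth background/ignore pixels are excluded.  Predicted
    background/ignore on an evaluated pixel counts as a miss for the
    true class (a false negative for it and nothing else).
    """
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth resolutions differ")
    g = gt.labels
    p = pred.labels
    evaluate = np.isin(g, FOREGROUND_CLASSES)
    if not evaluate.any():
        raise ValueError("no evaluable pixels (all background/ignore)")
    conf = np.zeros((_N, _N + 1), dtype=np.int64)   # extra col: pred invalid
    gi = g[evaluate].astype(np.int64) - 1
    pv = p[evaluate].astype(np.int64)
    pi = np.where(np.isin(pv, FOREGROUND_CLASSES), pv - 1, _N)
    np.add.at(conf, (gi, pi), 1)
    return conf


def jaccard_from_confusion(conf: np.ndarray) -> tuple[dict, float, list]:
    """Per-class Jaccard (%) and unweighted class average from a
    confusion matrix whose rows are true classes (an optional trailing
    column holds invalid predictions)."""
    core = conf[:, :_N]
    per_class = {}
    unsupported = []
    vals = []
    for j, cls in enumerate(FOREGROUND_CLASSES):
        tp = core[j, j]
        fn = conf[j].sum() - tp
        fp = core[:, j].sum() - tp
        support = conf[j].sum()
        if support == 0:
            per_class[cls] = float("nan")
            unsupported.append(cls)
            continue
        denom = tp + fp + fn
        per_class[cls] = 100.0 * tp / denom if denom else 100.0
        vals.append(per_class[cls])
    avg = float(np.mean(vals)) if vals else float("nan")
    return per_class, avg, unsupported


def confusion_and_jaccard(pred: LabelImage, gt: LabelImage) -> MetricsReport:
    """Eq.-(1)-style scoring of a predicted label image against GT."""
    conf = confusion_counts(pred, gt)
    per_class, avg, unsupported = jaccard_from_confusion(conf)
    return MetricsReport(confusion=conf[:, :_N],
                         per_class_jaccard=per_class,
                         class_average_jaccard=avg,
                         unsupported_classes=unsupported,
                         n_evaluated=int(conf.sum()))


def best_relabeling(overseg: Oversegmentation, gt: LabelImage) -> np.ndarray:
    """Max-intersection ground-truth label per superpixel (ties -> lower
    class code); superpixels without evaluable pixels get background."""
    g = gt.labels
    valid = (overseg.ids >= 0) & np.isin(g, FOREGROUND_CLASSES)
    ids = overseg.ids[valid]
    cls = g[valid].astype(np.int64)
    inter = np.zeros((overseg.n_segments, _N), dtype=np.int64)
    np.add.at(inter, (ids, cls - 1), 1)
    labels = np.argmax(inter, axis=1) + 1        # first max = lower code
    labels[inter.sum(axis=1) == 0] = BACKGROUND
    return labels.astype(np.int64)


def asa(overseg: Oversegmentation, gt: LabelImage) -> tuple[float, dict]:
    """Achievable segmentation accuracy of the oversegmentation.

    ASA = sum_k max_i |S_k ∩ G_i|  /  sum_i |G_i| over evaluable pixels,
    with the per-class *achievable* Jaccard of the induced best-case
    relabeling as a secondary output.
    """
    labels = best_relabeling(overseg, gt)
    pred = project_to_pixels(overseg, labels)
    conf = confusion_counts(pred, gt)
    total = conf.sum()
    if total == 0:
        raise ValueError("no evaluable pixels")
    value = float(np.trace(conf[:, :_N]) / total)
    per_class, _, _ = jaccard_from_confusion(conf)
    return value, per_class


def normalize_confusion(counts: np.ndarray) -> np.ndarray:
    """Row-stochastic confusion; all-zero rows stay zero."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("confusion counts must be non-negative")
    sums = counts.sum(axis=1, keepdims=True)
    out = np.divide(counts, sums, out=np.zeros_like(counts),
                    where=sums > 0)
    return out


def pooled_report(pairs, overseg_pairs=None) -> MetricsReport:
    """Pool confusion counts over (pred, gt) image pairs, then score.

    ``overseg_pairs`` — matching (overseg, gt) pairs — additionally
    pools the ASA bound and achievable Jaccard over the same pixels.
    """
    conf = np.zeros((_N, _N + 1), dtype=np.int64)
    for pred, gt in pairs:
        conf += confusion_counts(pred, gt)
    per_class, avg, unsupported = jaccard_from_confusion(conf)
    report = MetricsReport(confusion=conf[:, :_N],
                           per_class_jaccard=per_class,
                           class_average_jaccard=avg,
                           unsupported_classes=unsupported,
                           n_evaluated=int(conf.sum()))
    if overseg_pairs is not None:
        aconf = np.zeros((_N, _N + 1), dtype=np.int64)
        for ov, gt in overseg_pairs:
            pred = project_to_pixels(ov, best_relabeling(ov, gt))
            aconf += confusion_counts(pred, gt)
        report.asa = float(np.trace(aconf[:, :_N]) / aconf.sum())
        report.achievable_jaccard, _, _ = jaccard_from_confusion(aconf)
    return report
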