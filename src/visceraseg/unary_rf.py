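"""Random-forest unary classification of superpixels.

The forest assigns each superpixel a probability vector over the four
organ classes; these probabilities are the unary potentials refined by
the CRF.  The heavy class skew (~70% miscellaneous tissue) is
compensated with per-class prior weights, by default the inverse class
frequency of the training superpixels.  The tree count can be chosen by
out-of-bag error convergence, and the remaining hyperparameters by a
group-aware cross-validated grid search (views of one viscera set never
straddle folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, make_scorer
from sklearn.model_selection import GridSearchCV, GroupKFold

from .data_model import CLASS_NAMES, FOREGROUND_CLASSES
from .overseg import Oversegmentation


@dataclass
class RFConfig:
    n_trees: int | str = 200              # int or "auto" (OOB convergence)
    class_priors: Optional[dict] = None   # class code -> weight; None = inverse freq
    cv_grid: Optional[dict] = field(default_factory=lambda: {
        "max_depth": [8, 16, None],
        "min_samples_leaf": [1, 5, 20],
        "max_features": ["sqrt", 0.3]})
    cv_folds: int = 5
    oob_tol: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_priors is not None:
            for cls in FOREGROUND_CLASSES:
                if self.class_priors.get(cls, 0) <= 0:
                    raise ValueError(
                        f"prior for class {CLASS_NAMES[cls]} must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class UnaryPotentials:
    """S x 4 class-probability rows (misc, heart, liver, lung)."""

    proba: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.proba < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.proba.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")


def superpixel_labels_from_gt(overseg: Oversegmentation, gt) -> tuple[np.ndarray, np.ndarray]:
    """Majority ground-truth class per superpixel plus a training mask.

    Ignore and background pixels do not vote; superpixels whose members
    are all ignore/background are masked out of training.  Vote ties go
    to the lower class code.
    """
    labels = gt.labels if hasattr(gt, "labels") else np.asarray(gt)
    if labels.shape != overseg.ids.shape:
        raise ValueError("ground truth and oversegmentation resolutions differ")
    valid = (overseg.ids >= 0) & np.isin(labels, FOREGROUND_CLASSES)
    ids = overseg.ids[valid]
    cls = labels[valid].astype(np.int64)
    votes = np.zeros((overseg.n_segments, max(FOREGROUND_CLASSES) + 1),
                     dtype=np.int64)
    np.add.at(votes, (ids, cls), 1)
    keep = votes.sum(axis=1) > 0
    # argmax over class codes 1..4; ties resolve to the lower code
    sp_labels = np.argmax(votes[:, 1:], axis=1) + 1
    sp_labels[~keep] = 0
    return sp_labels, keep


def _priors_from_labels(labels: np.ndarray) -> dict:
    counts = {cls: np.count_nonzero(labels == cls)
              for cls in FOREGROUND_CLASSES}
    total = sum(counts.values())
    return {cls: total / (len(FOREGROUND_CLASSES) * c) if c else 1.0
            for cls, c in counts.items()}


def select_n_trees_by_oob(features: np.ndarray, labels: np.ndarray,
                          config: Optional[RFConfig] = None,
                          grid: tuple = (25, 50, 100, 200, 400, 800)) -> int:
    """Smallest tree count on a doubling grid at which the out-of-bag
    error stops improving by more than ``oob_tol``."""
    config = config or RFConfig()
    if len(np.unique(labels)) < 2:
        raise ValueError("OOB tree selection needs at least 2 classes")
    rf = RandomForestClassifier(
        n_estimators=grid[0], oob_score=True, warm_start=True,
        random_state=config.seed, n_jobs=1)
    prev_err = None
    for n in grid:
        rf.set_params(n_estimators=n)
        rf.fit(features, labels)
        err = 1.0 - rf.oob_score_
        if prev_err is not None and prev_err - err < config.oob_tol:
            return n
        prev_err = err
    return grid[-1]


def train_rf(features: np.ndarray, labels: np.ndarray,
             config: Optional[RFConfig] = None,
             groups: Optional[np.ndarray] = None) -> RandomForestClassifier:
    """Train the class-weighted forest, optionally grid-searching
    hyperparameters with group-aware CV (grouped by viscera set)."""
    config = config or RFConfig()
    present = set(np.unique(labels).tolist())
    for cls in FOREGROUND_CLASSES:
        if cls not in present:
            raise ValueError(f"class {CLASS_NAMES[cls]} missing from "
                             "training data")
    priors = config.class_priors or _priors_from_labels(labels)
    n_trees = config.n_trees
    if n_trees == "auto":
        n_trees = select_n_trees_by_oob(features, labels, config)
    rf = RandomForestClassifier(
        n_estimators=int(n_trees), class_weight={int(k): float(v)
                                                 for k, v in priors.items()},
        random_state=config.seed, n_jobs=1)
    if config.cv_grid:
        folds = config.cv_folds
        if groups is not None:
            n_groups = len(np.unique(groups))
            folds = min(folds, n_groups)
            cv = GroupKFold(n_splits=folds)
            split = cv.split(features, labels, groups)
        else:
            split = min(folds, np.bincount(labels).min() if labels.size else 2)
        search = GridSearchCV(
            rf, config.cv_grid, cv=split,
            scoring=make_scorer(balanced_accuracy_score), n_jobs=1)
        search.fit(features, labels)
        return search.best_estimator_
    rf.fit(features, labels)
    return rf


def predict_proba(model: RandomForestClassifier,
                  features: np.ndarray) -> UnaryPotentials:
    """Class-probability rows ordered (misc, heart, liver, lung)."""
    raw = model.predict_proba(features)
    proba = np.zeros((len(features), len(FOREGROUND_CLASSES)))
    for j, cls in enumerate(model.classes_):
        proba[:, list(FOREGROUND_CLASSES).index(int(cls))] = raw[:, j]
    return UnaryPotentials(proba=proba)
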