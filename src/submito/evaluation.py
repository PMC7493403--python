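"""Scoring: per-class Matthews correlation coefficient and cross-validation.

Each compartment is scored one-vs-rest: the 4x4 confusion matrix is
binarized for the class of interest and

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the conventional value 0 when the denominator vanishes.  MCC is the
Pearson correlation between the binarized predicted and true indicator
vectors, which makes it robust to class imbalance — the reason it is the
metric of choice for compartments with very unequal membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cnn_model import (
    CompartmentLabel,
    Model,
    ModelConfig,
    N_CLASSES,
    PredictionResult,
    TrainConfig,
    build_model,
    predict_many,
    train,
)
from .encoding import EncodedProtein


@dataclass(frozen=True)
class ConfusionMatrix4:
    """4x4 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("confusion matrix must be 4x4 with non-negative counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix4") -> "ConfusionMatrix4":
        return ConfusionMatrix4(self.counts + other.counts)


def confusion(
    preds: Sequence[PredictionResult], truth: Sequence[tuple[str, CompartmentLabel]]
) -> ConfusionMatrix4:
    """Tabulate predictions against truth, aligned by protein id."""
    if len(preds) != len(truth):
        raise ValueError(f"{len(preds)} predictions vs {len(truth)} truth labels")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for pred, (pid, true_label) in zip(preds, truth):
        if pred.protein_id != pid:
            raise ValueError(
                f"prediction for {pred.protein_id!r} aligned with truth for {pid!r}"
            )
        counts[int(true_label), int(pred.label)] += 1
    return ConfusionMatrix4(counts)


def binarize(cm: ConfusionMatrix4, k: CompartmentLabel | int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class k."""
    k = int(k)
    c = cm.counts
    tp = int(c[k, k])
    fn = int(c[k, :].sum() - c[k, k])
    fp = int(c[:, k].sum() - c[k, k])
    tn = int(c.sum() - tp - fn - fp)
    return tp, tn, fp, fn


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    num = tp * tn - fp * fn
    den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if den == 0.0:
        return 0.0
    return num / den


def per_class_mcc(cm: ConfusionMatrix4, k: CompartmentLabel | int) -> float:
    """One-vs-rest Matthews correlation for compartment k, in [-1, 1]."""
    return mcc_from_counts(*binarize(cm, k))


def all_class_mcc(cm: ConfusionMatrix4) -> dict[CompartmentLabel, float]:
    return {k: per_class_mcc(cm, k) for k in CompartmentLabel}


def cross_validate(
    data: Sequence[tuple[EncodedProtein, CompartmentLabel]],
    k_folds: int,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    model_factory: Callable[[ModelConfig], Model] = build_model,
) -> tuple[list[ConfusionMatrix4], dict[CompartmentLabel, float]]:
    """Stratified k-fold cross-validation of the compartment predictor.

    Folds split every class as evenly as possible; the pooled per-class
    MCCs are computed on the sum of the per-fold confusion matrices.
    Returns (per-fold matrices, pooled per-class MCC).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    ys = np.array([int(label) for _, label in data])
    class_counts = np.bincount(ys, minlength=N_CLASSES)
    small = [CompartmentLabel(i).name for i, c in enumerate(class_counts) if 0 < c < k_folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer members than {k_folds} folds; "
            "use fewer folds"
        )
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_matrices: list[ConfusionMatrix4] = []
    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(ys)), ys)):
        model = model_factory(model_config)
        train(model, [data[i] for i in train_idx], train_config)
        test_pairs = [data[i] for i in test_idx]
        preds = predict_many(model, [e for e, _ in test_pairs])
        truth = [(e.protein_id, label) for e, label in test_pairs]
        fold_matrices.append(confusion(preds, truth))
    pooled = ConfusionMatrix4(sum(m.counts for m in fold_matrices))
    return fold_matrices, all_class_mcc(pooled)


def fold_assignment(
    labels: Sequence[int], k_folds: int, seed: int = 0
) -> list[np.ndarray]:
    """Test-fold index sets of the stratified split (exposed for inspection)."""
    ys = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(ys)), ys)]
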