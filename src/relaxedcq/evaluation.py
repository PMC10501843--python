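"""Classification metrics, cross-entropy loss, and cross-validated training.

Metrics follow the usual confusion-matrix definitions, reported in percent:
accuracy, precision, recall, F1.  A published variant of the recall
denominator (TP / (TN + FN)) is available behind a flag for bit-faithful
reproduction attempts; the default is the standard TP / (TP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .elm import ELMModel, TrainingSet, hidden_matrix, predict, train
from .solvers import Method, SolverConfig

__all__ = [
    "ConfusionCounts",
    "FoldPlan",
    "CVResult",
    "confusion",
    "metrics",
    "bce_loss",
    "kfold",
    "cross_validate",
]

CLIP = 1e-7  # raw network outputs are clipped to [CLIP, 1-CLIP] before the log


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts, literal_recall: bool = False) -> dict[str, float]:
    """Accuracy, precision, recall and F1 in percent.

    Zero denominators yield ``nan`` for the affected metric (flagged, not a
    crash).  ``literal_recall=True`` switches the recall denominator to
    TN + FN, reproducing a published variant of the formula.
    """
    if c.total == 0:
        raise ValueError("no samples to evaluate")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    acc = ratio(c.tp + c.tn, c.total)
    prec = ratio(c.tp, c.tp + c.fp)
    rec = ratio(c.tp, c.tn + c.fn) if literal_recall else ratio(c.tp, c.tp + c.fn)
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def bce_loss(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Binary cross-entropy with the outputs clipped away from 0 and 1."""
    o = np.clip(np.asarray(outputs, dtype=float).ravel(), CLIP, 1.0 - CLIP)
    t = np.asarray(targets, dtype=float).ravel()
    if o.shape != t.shape:
        raise ValueError("outputs and targets differ in length")
    return float(-np.mean(t * np.log(o) + (1.0 - t) * np.log(1.0 - o)))


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of samples into k folds."""

    k: int
    assignments: np.ndarray  # sample index -> fold id in [0, k)
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


def kfold(data: TrainingSet, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold plan; per-fold class counts are proportional to within 1."""
    if k < 2:
        raise ValueError("k must be at least 2")
    y = data.targets.astype(int)
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(data.n_samples, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(data.features, y)):
        assign[test_idx] = fold
    return FoldPlan(k=k, assignments=assign, seed=seed)


@dataclass
class CVResult:
    """Per-fold and aggregate outcome of cross-validated ELM training."""

    fold_metrics: list[dict[str, float]]
    fold_counts: list[ConfusionCounts]
    fold_iterations: list[int]
    fold_times: list[float]
    curves: list[dict[str, np.ndarray]]  # train/val loss and accuracy per iteration
    mean_metrics: dict[str, float] = field(default_factory=dict)

    @property
    def pooled_counts(self) -> ConfusionCounts:
        total = self.fold_counts[0]
        for c in self.fold_counts[1:]:
            total = total + c
        return total


def _curves_from_trace(
    model: ELMModel,
    iterates: list[np.ndarray],
    H_train: np.ndarray,
    y_train: np.ndarray,
    H_val: np.ndarray,
    y_val: np.ndarray,
) -> dict[str, np.ndarray]:
    tr_loss, va_loss, tr_acc, va_acc = [], [], [], []
    for w in iterates:
        o_tr = H_train @ w
        o_va = H_val @ w
        tr_loss.append(bce_loss(o_tr, y_train))
        va_loss.append(bce_loss(o_va, y_val))
        tr_acc.append(100.0 * np.mean((o_tr >= 0.5) == (y_train == 1)))
        va_acc.append(100.0 * np.mean((o_va >= 0.5) == (y_val == 1)))
    return {
        "train_loss": np.asarray(tr_loss),
        "val_loss": np.asarray(va_loss),
        "train_acc": np.asarray(tr_acc),
        "val_acc": np.asarray(va_acc),
    }


def cross_validate(
    data: TrainingSet,
    n_hidden: int = 160,
    constraint: str = "l2_ball",
    gamma: float = 17.0,
    method: Method | str = Method.IMRCQM,
    config: Optional[SolverConfig] = None,
    k: int = 5,
    seed: int = 0,
    record_curves: bool = True,
    literal_recall: bool = False,
) -> CVResult:
    """Train one ELM per fold and aggregate held-out metrics.

    The hidden layer is redrawn per fold from ``seed + fold`` so folds are
    independent replicates.  Training/validation loss and accuracy curves
    are replayed from the solver's iterate trace against both splits.
    The aggregate is the unweighted mean over folds; the pooled confusion
    counts are also kept so both aggregations are available.
    """
    plan = kfold(data, k=k, seed=seed)
    result = CVResult([], [], [], [], [])
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        train_set = TrainingSet(data.features[tr], data.targets[tr])
        model = ELMModel(n_hidden=n_hidden, n_features=data.n_features, seed=seed + fold)
        model, run = train(
            model,
            train_set,
            constraint=constraint,
            gamma=gamma,
            method=method,
            config=config,
            keep_iterates=record_curves,
        )
        y_pred = predict(model, data.features[te])
        counts = confusion(data.targets[te], y_pred)
        result.fold_counts.append(counts)
        result.fold_metrics.append(metrics(counts, literal_recall=literal_recall))
        result.fold_iterations.append(run.n_iter)
        result.fold_times.append(run.elapsed)
        if record_curves:
            H_tr = hidden_matrix(model, data.features[tr])
            H_te = hidden_matrix(model, data.features[te])
            result.curves.append(
                _curves_from_trace(
                    model, run.iterates, H_tr, data.targets[tr], H_te, data.targets[te]
                )
            )
    keys = result.fold_metrics[0].keys()
    result.mean_metrics = {
        key: float(np.mean([m[key] for m in result.fold_metrics])) for key in keys
    }
    return result
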