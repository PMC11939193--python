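"""Training protocol, classification metrics and k-fold cross-validation.

Training follows the production protocol of the classifier: Adam on
cross-entropy, batch size 128, early stopping when the validation loss
has not improved for a fixed number of consecutive epochs, returning the
weights of the best validation epoch.  The default learning rate is the
production value (1e-5); desk-scale experiments on small synthetic
cohorts typically pass a larger one.

The confusion-matrix conventions treat hypertensive as the positive
class: accuracy = (TP+TN)/(P+N), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP).  Both the positive-class F1
(2*Prec*Rec/(Prec+Rec)) and the macro (unweighted two-class) F1 are
reported.  Undefined ratios are flagged and surfaced as NaN, never
silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import BHNet, BHNetConfig
from .nn import Adam, backward
from .nn import functional as F
from .signal_core import BcgSegment


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-5
    early_stopping_patience: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1_positive: float
    macro_f1: float
    roc_auc: float
    undefined: list[str] = field(default_factory=list)


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def classification_metrics(labels, probabilities, threshold: float = 0.5
                           ) -> tuple[ConfusionCounts, ClassificationMetrics]:
    """Counts and metrics from hypertensive-class probabilities.

    ``probabilities`` may be a (n,) positive-class score vector or an
    (n, 2) probability matrix.
    """
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.ndim == 2:
        probabilities = probabilities[:, 1]
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be 0 (control) or 1 (hypertensive)")
    pred = probabilities > threshold
    counts = ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )
    und: list[str] = []
    accuracy = _ratio(counts.tp + counts.tn, counts.p + counts.n, "accuracy", und)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", und)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", und)
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", und)
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        und.append("f1_positive")
        f1_pos = float("nan")
    else:
        f1_pos = 2 * precision * sensitivity / (precision + sensitivity)
    # macro F1: unweighted mean of per-class F1 scores
    prec_neg = _ratio(counts.tn, counts.tn + counts.fn, "precision_negative", und)
    if np.isnan(prec_neg) or np.isnan(specificity) or prec_neg + specificity == 0:
        und.append("macro_f1")
        macro_f1 = float("nan")
    else:
        f1_neg = 2 * prec_neg * specificity / (prec_neg + specificity)
        macro_f1 = (f1_pos + f1_neg) / 2 if not np.isnan(f1_pos) else float("nan")
    if len(np.unique(labels)) < 2:
        und.append("roc_auc")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, probabilities))
    return counts, ClassificationMetrics(accuracy, sensitivity, specificity,
                                         precision, f1_pos, macro_f1, auc, und)


def segments_to_arrays(segments: Sequence[BcgSegment]
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack segments into (X, y, subject_ids) model arrays."""
    x = np.stack([s.samples for s in segments]).astype(np.float32)
    y = np.array([s.label for s in segments], dtype=int)
    groups = np.array([s.subject_id for s in segments])
    return x, y, groups


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    def __len__(self) -> int:
        return len(self.val_loss)


def _eval_loss(model: BHNet, x: np.ndarray, y: np.ndarray,
               batch_size: int) -> tuple[float, float]:
    probs = model.predict_proba(x, batch_size=batch_size)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train_model(model: BHNet, train_data, val_data,
                config: TrainConfig | None = None) -> TrainHistory:
    """Train in place; restores the best-validation-loss weights.

    ``train_data`` / ``val_data`` are ``(X, y)`` with X of shape
    (n, input_length) and integer class labels.
    """
    config = config or TrainConfig()
    x_tr, y_tr = np.asarray(train_data[0], dtype=np.float32), np.asarray(train_data[1])
    x_va, y_va = np.asarray(val_data[0], dtype=np.float32), np.asarray(val_data[1])
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_loss = np.inf
    best_state = model.state_dict()
    since_best = 0
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.forward(x_tr[idx])
            logits = model.activations["logits"]
            loss = F.cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            backward(loss)
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_loss.append(epoch_loss / len(order))
        val_loss, val_acc = _eval_loss(model, x_va, y_va, config.batch_size)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                history.stopped_early = True
                break
    model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate_model(model: BHNet, x, y, threshold: float = 0.5
                   ) -> tuple[ConfusionCounts, ClassificationMetrics]:
    probs = model.predict_proba(np.asarray(x, dtype=np.float32))
    return classification_metrics(np.asarray(y), probs, threshold)


def assign_folds(y: np.ndarray, groups: np.ndarray | None, k: int,
                 grouping: str, seed: int) -> np.ndarray:
    """Deterministic fold labels per sample.

    ``segment`` mode shuffles segments; ``subject`` mode shuffles subjects
    and keeps every subject's segments in one fold.
    """
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    if grouping == "segment":
        folds = np.arange(n) % k
        rng.shuffle(folds)
        return folds
    if grouping != "subject":
        raise ValueError("grouping must be 'segment' or 'subject'")
    if groups is None:
        raise ValueError("subject grouping needs per-segment subject ids")
    subjects = np.unique(groups)
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    order = rng.permutation(len(subjects))
    fold_of = {subjects[j]: i % k for i, j in enumerate(order)}
    return np.array([fold_of[g] for g in groups])


def cross_validate(x, y, model_config: BHNetConfig,
                   train_config: TrainConfig | None = None, k: int = 10,
                   grouping: str = "segment", groups=None,
                   model_builder: Callable[[BHNetConfig], BHNet] | None = None
                   ) -> dict:
    """k-fold cross-validation; metrics averaged arithmetically over folds.

    Each fold's held-out part doubles as the early-stopping validation
    set, mirroring a protocol that reports averaged validation metrics.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    train_config = train_config or TrainConfig()
    builder = model_builder or (lambda cfg: BHNet(cfg))
    folds = assign_folds(y, None if groups is None else np.asarray(groups),
                         k, grouping, train_config.seed)
    per_fold = []
    fields = ("accuracy", "sensitivity", "specificity", "precision",
              "f1_positive", "macro_f1", "roc_auc")
    for fold in range(k):
        test = folds == fold
        model = builder(model_config)
        train_model(model, (x[~test], y[~test]), (x[test], y[test]), train_config)
        _, metrics = evaluate_model(model, x[test], y[test])
        per_fold.append(metrics)
    mean = {f: float(np.mean([getattr(m, f) for m in per_fold])) for f in fields}
    return {"folds": per_fold, "mean": mean, "fold_assignment": folds}
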