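"""Training protocol and evaluation metrics.

Splits are stratified at the segment level: an outer stratified 5-fold
scheme (80/20) whose training share is further split 87.5/12.5, giving an
overall 70:10:20 train/validation/test ratio per fold.  Training uses
sparse categorical cross-entropy with the Nadam optimizer, learning-rate
decay on a validation-loss plateau, and early stopping.

Metrics follow the one-vs-rest reduction: per class TP/TN/FP/FN yield
accuracy, specificity, sensitivity, precision and F1; macro values are
unweighted means over the six classes.  Segment-level splitting can leak
a patient across folds; pass ``groups`` to the split helpers to group by
patient instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._nn import Nadam, softmax_cross_entropy
from .model import MultiHeadClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "MetricsReport", "stratified_split", "make_folds",
    "train_model", "confusion_matrix", "binary_metrics_from_counts",
    "multiclass_metrics", "evaluate", "cross_validate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the selected final values."""

    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 50
    optimizer: str = "nadam"
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    min_lr: float = 1e-5
    early_stop_patience: int = 10
    restore_best: bool = True
    seed: int = 0


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class and macro one-vs-rest metrics."""

    confusion: np.ndarray
    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    auc_ovr: dict[int, float] = field(default_factory=dict)
    roc_points: dict[int, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {int(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "accuracy": self.accuracy,
            "auc_ovr": {int(k): v for k, v in self.auc_ovr.items()},
        }


def stratified_split(labels, ratios=(0.70, 0.10, 0.20), seed: int = 0):
    """Disjoint, exhaustive (train, val, test) index sets, stratified.

    Within each class, sizes follow the ratios by largest-remainder
    rounding, so per-class proportions land within one sample of the
    requested split.
    """
    labels = np.asarray(labels)
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    n_active = sum(r > 0 for r in ratios)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < max(3, n_active) and n_active == 3:
            raise ValueError(f"class {cls} has only {len(idx)} samples; need >= 3")
        rng.shuffle(idx)
        exact = np.array(ratios) * len(idx)
        counts = np.floor(exact).astype(int)
        order = np.argsort(-(exact - counts))
        for j in order[: len(idx) - counts.sum()]:
            counts[j] += 1
        splits = np.split(idx, np.cumsum(counts)[:-1])
        for p, s in zip(parts, splits):
            p.extend(s.tolist())
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def make_folds(labels, k: int = 5, seed: int = 0):
    """Stratified k-fold partitions [(train_idx, test_idx), ...]."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"classes {small.tolist()} have fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _state_arrays(model) -> list[np.ndarray]:
    """All mutable model state: parameters plus batch-norm running stats."""
    from ._nn import BatchNorm
    arrays = [p.value for p in model.params()]
    stacks = (list(model.heads.values()) + [model.classifier]
              if hasattr(model, "heads") else [model])
    for seq in stacks:
        for layer in getattr(seq, "layers", []):
            if isinstance(layer, BatchNorm):
                arrays += [layer.running_mean, layer.running_var]
    return arrays


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _forward_loss(model: MultiHeadClassifier, xs, y, train: bool):
    logits = model.forward(xs, train=train)
    loss, grad = softmax_cross_entropy(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, grad, acc


def _eval_in_batches(model, xs, y, batch_size: int):
    losses, correct = [], 0
    for start in range(0, len(y), batch_size):
        sl = slice(start, start + batch_size)
        yb = y[sl]
        loss, _, acc = _forward_loss(model, [x[sl] for x in xs], yb, train=False)
        losses.append(loss * len(yb))
        correct += int(round(acc * len(yb)))
    return sum(losses) / len(y), correct / len(y)


def train_model(model: MultiHeadClassifier, train_data, val_data,
                cfg: TrainConfig = TrainConfig()):
    """Train with Nadam + plateau LR decay + early stopping.

    ``train_data``/``val_data`` are ``(xs, y)`` with ``xs`` the list of the
    three feature batches.  Returns ``(model, history)`` where history has
    per-epoch train/val loss and accuracy and the learning rate.  With
    ``cfg.restore_best`` the weights (and batch-norm statistics) of the
    best validation-loss epoch are restored at the end, so the monitored
    quantity also selects the returned model.
    """
    xs, y = train_data
    if len(y) == 0 or len(val_data[1]) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Nadam(model.params(), lr=cfg.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [],
               "val_acc": [], "lr": []}
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    state = _state_arrays(model)
    stale_lr = stale_stop = 0
    for epoch in range(cfg.epochs):
        ep_loss, ep_correct, n_seen = 0.0, 0, 0
        for batch in _batches(len(y), cfg.batch_size, rng):
            xb = [x[batch] for x in xs]
            yb = y[batch]
            opt.zero_grad()
            loss, grad, acc = _forward_loss(model, xb, yb, train=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch}; lr={opt.lr:.2e}")
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(yb)
            ep_correct += int(round(acc * len(yb)))
            n_seen += len(yb)
        val_loss, val_acc = _eval_in_batches(model, *val_data, cfg.batch_size)
        history["train_loss"].append(ep_loss / n_seen)
        history["train_acc"].append(ep_correct / n_seen)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        logger.info("epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                    epoch, history["train_loss"][-1], history["train_acc"][-1],
                    val_loss, val_acc)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stale_lr = stale_stop = 0
            if cfg.restore_best:
                best_state = [a.copy() for a in state]
        else:
            stale_lr += 1
            stale_stop += 1
            if stale_lr >= cfg.plateau_patience:
                opt.lr = max(cfg.min_lr, opt.lr * cfg.plateau_factor)
                stale_lr = 0
            if stale_stop >= cfg.early_stop_patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if cfg.restore_best and best_state is not None:
        for dst, src in zip(state, best_state):
            dst[...] = src
    return model, history


def confusion_matrix(y_true, y_pred, n_classes: int = 6) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


def binary_metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, specificity, sensitivity, precision and F1 from counts.

    Zero-denominator metrics are reported as 0 with a warning.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + tn + fn + fp, "accuracy")
    specificity = ratio(tn, tn + fp, "specificity")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    precision = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * precision * sensitivity, precision + sensitivity, "f1")
    return {"accuracy": accuracy, "specificity": specificity,
            "sensitivity": sensitivity, "precision": precision, "f1": f1}


def multiclass_metrics(confusion: np.ndarray) -> MetricsReport:
    """One-vs-rest reduction of a square confusion matrix."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = confusion.sum()
    per_class = {}
    for c in range(confusion.shape[0]):
        tp = int(confusion[c, c])
        fn = int(confusion[c].sum() - tp)
        fp = int(confusion[:, c].sum() - tp)
        tn = int(total - tp - fn - fp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_class[c] = binary_metrics_from_counts(tp, tn, fp, fn)
    keys = next(iter(per_class.values())).keys()
    macro = {k: float(np.mean([m[k] for m in per_class.values()])) for k in keys}
    overall = float(np.trace(confusion) / total) if total else 0.0
    return MetricsReport(confusion=confusion, per_class=per_class,
                         macro=macro, accuracy=overall)


def evaluate(model: MultiHeadClassifier, test_data,
             batch_size: int = 32) -> MetricsReport:
    """Deterministic eval-mode metrics plus per-class one-vs-rest AUC."""
    xs, y = test_data
    if len(y) == 0:
        raise ValueError("test set is empty")
    probs = np.concatenate([
        model.predict_proba([x[s:s + batch_size] for x in xs])
        for s in range(0, len(y), batch_size)])
    preds = probs.argmax(axis=1)
    n_classes = probs.shape[1]
    report = multiclass_metrics(confusion_matrix(y, preds, n_classes))
    for c in range(n_classes):
        binary = (y == c).astype(int)
        if binary.min() == binary.max():
            continue  # class absent (or alone) in the test set
        fpr, tpr, _ = roc_curve(binary, probs[:, c])
        report.auc_ovr[c] = float(auc(fpr, tpr))
        report.roc_points[c] = (fpr, tpr)
    return report


def cross_validate(build_model, xs, y, k: int = 5,
                   cfg: TrainConfig = TrainConfig(), val_fraction: float = 0.125):
    """Stratified k-fold evaluation reporting per-fold and mean accuracy.

    Each fold's training share is further split (stratified) into train
    and validation, so with k = 5 and ``val_fraction`` = 0.125 the overall
    ratio is 70:10:20 per fold.  ``build_model`` maps a seed to a fresh
    model.  Per-fold accuracies are reported alongside their mean — the
    mean of fold accuracies, not the accuracy of a pooled confusion
    matrix — and both granularities are logged and returned.
    """
    folds = make_folds(y, k=k, seed=cfg.seed)
    reports: list[MetricsReport] = []
    for i, (tr_all, te) in enumerate(folds):
        tr, va, _ = stratified_split(
            y[tr_all], ratios=(1.0 - val_fraction, val_fraction, 0.0),
            seed=cfg.seed + i)
        tr, va = tr_all[tr], tr_all[va]
        model = build_model(cfg.seed + i)
        model, _ = train_model(model, ([x[tr] for x in xs], y[tr]),
                               ([x[va] for x in xs], y[va]), cfg)
        report = evaluate(model, ([x[te] for x in xs], y[te]),
                          batch_size=cfg.batch_size)
        logger.info("fold %d: accuracy %.4f", i, report.accuracy)
        reports.append(report)
    fold_accs = [r.accuracy for r in reports]
    mean_acc = float(np.mean(fold_accs))
    logger.info("fold accuracies %s | mean %.4f", fold_accs, mean_acc)
    return {"per_fold": reports, "fold_accuracies": fold_accs,
            "mean_accuracy": mean_acc}
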