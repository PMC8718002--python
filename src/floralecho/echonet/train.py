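"""Training loop, early stopping, and evaluation with binomial intervals."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .chunks import EchoChunk
from .features import EchoRenderer
from .net import Adam, EchoCNN

__all__ = ["Hyper", "TrainReport", "train", "evaluate", "clopper_pearson"]


@dataclass(frozen=True)
class Hyper:
    """Training hyperparameters (cross-entropy loss, Adam optimizer)."""

    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-4
    patience: int = 8  # early-stopping patience on validation loss
    seed: int = 0


@dataclass
class TrainReport:
    """Learning curves, test confusion matrix and per-syndrome accuracy."""

    class_order: List[str]
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    train_acc: List[float] = field(default_factory=list)
    val_acc: List[float] = field(default_factory=list)
    epochs_run: int = 0
    early_stopped: bool = False
    test_accuracy: Optional[float] = None
    confusion: Optional[np.ndarray] = None  # rows = true class
    per_syndrome: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return json.dumps(d, indent=2)


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a rate."""
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="beta")
    return float(lo), float(hi)


def _dataset(
    chunks: Sequence[EchoChunk], renderer: EchoRenderer, class_order: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    index = {c: i for i, c in enumerate(class_order)}
    x = np.stack([renderer.chunk_tensor(c) for c in chunks])
    y = np.array([index[c.species_id] for c in chunks], dtype=int)
    return x, y


def _eval_loss_acc(model: EchoCNN, x: np.ndarray, y: np.ndarray,
                   batch_size: int) -> Tuple[float, float]:
    probs = model.predict_proba(x, batch_size=batch_size)
    loss = float(-np.mean(np.log(probs[np.arange(y.size), y] + 1e-12)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train(
    model: EchoCNN,
    train_chunks: Sequence[EchoChunk],
    val_chunks: Sequence[EchoChunk],
    renderer: EchoRenderer,
    class_order: Sequence[str],
    hyper: Hyper = Hyper(),
) -> TrainReport:
    """Train with shuffled batches, unshuffled validation, early stopping.

    Spectrograms are produced on demand by the renderer from IR + call. The
    best-validation-loss weights are restored before returning. A NaN loss
    aborts with diagnostics rather than continuing silently.
    """
    rng = np.random.default_rng(hyper.seed)
    x_train, y_train = _dataset(train_chunks, renderer, class_order)
    x_val, y_val = _dataset(val_chunks, renderer, class_order)
    opt = Adam(lr=hyper.learning_rate)
    report = TrainReport(class_order=list(class_order))
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    for epoch in range(hyper.epochs):
        order = rng.permutation(len(train_chunks))
        losses = []
        correct = 0
        for start in range(0, len(order), hyper.batch_size):
            sel = order[start : start + hyper.batch_size]
            loss, grads, probs = model.loss_and_grads(x_train[sel], y_train[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at epoch {epoch + 1}, "
                    f"batch starting {start} (lr={hyper.learning_rate})"
                )
            opt.step(model.params, grads)
            losses.append(loss)
            correct += int(np.sum(probs.argmax(axis=1) == y_train[sel]))
        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val, hyper.batch_size)
        report.train_loss.append(float(np.mean(losses)))
        report.train_acc.append(correct / len(order))
        report.val_loss.append(val_loss)
        report.val_acc.append(val_acc)
        report.epochs_run = epoch + 1
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= hyper.patience:
                report.early_stopped = True
                break
    model.load_state_dict(best_state)
    return report


def evaluate(
    model: EchoCNN,
    test_chunks: Sequence[EchoChunk],
    renderer: EchoRenderer,
    class_order: Sequence[str],
    syndrome_by_species: Optional[Mapping[str, str]] = None,
    report: Optional[TrainReport] = None,
    batch_size: int = 64,
) -> TrainReport:
    """Test-set accuracy, confusion matrix and per-syndrome binomial CIs.

    The confusion matrix has true classes in rows; per-syndrome accuracy
    pools the chunks of all species of that syndrome and carries an exact 95%
    Clopper-Pearson interval.
    """
    if report is None:
        report = TrainReport(class_order=list(class_order))
    x, y = _dataset(test_chunks, renderer, class_order)
    probs = model.predict_proba(x, batch_size=batch_size)
    pred = probs.argmax(axis=1)
    n_cls = len(class_order)
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    report.confusion = confusion
    report.test_accuracy = float(np.mean(pred == y))
    if syndrome_by_species is not None:
        syndromes = np.array([syndrome_by_species[class_order[i]] for i in y])
        for syn in sorted(set(syndromes)):
            mask = syndromes == syn
            n = int(mask.sum())
            k = int(np.sum(pred[mask] == y[mask]))
            lo, hi = clopper_pearson(k, n)
            report.per_syndrome[syn] = {
                "accuracy": k / n, "ci_low": lo, "ci_high": hi, "n": n,
            }
    return report
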