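"""Training loop with validation-driven checkpoint selection.

The model learns from training saccades' *working* labels (possibly
corrected by the map-based relabeling) but is selected on *register*-level
recall computed from the validation registers' original diagnoses: after
every epoch the validation saccades are predicted, aggregated per
register by majority vote, and the checkpoint maximizing the recall
compromise — the minimum of the control and presymptomatic recalls — is
kept (ties go to the higher macro recall, then to the earlier epoch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..core_data import CLASSES, DiagnosisClass, Saccade, SaccadeDataset
from ..evaluation import classify_register, confusion_matrix, class_metrics
from . import layers as L
from .model import Adam, CNNLSTM, ModelConfig

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "compromise_score",
    "train_with_selection",
    "predict_saccade_labels",
]

_LABELS = list(CLASSES)


@dataclass(frozen=True)
class TrainingConfig:
    max_epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    selection: str = "recall_compromise"  # or "accuracy"

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.selection not in ("recall_compromise", "accuracy"):
            raise ValueError(f"unknown selection rule {self.selection!r}")


@dataclass
class TrainedModel:
    model: CNNLSTM
    training_config: TrainingConfig
    history: list[dict] = field(default_factory=list)
    selected_epoch: int = 0

    @property
    def config(self) -> ModelConfig:
        return self.model.config


def compromise_score(per_class_recalls: dict[DiagnosisClass, float]) -> float:
    """min(recall_C, recall_P): the score of the control/presymptomatic
    sensitivity compromise used for checkpoint and threshold selection."""
    try:
        r_c = per_class_recalls[DiagnosisClass.C]
        r_p = per_class_recalls[DiagnosisClass.P]
    except KeyError as exc:
        raise ValueError(f"missing recall for class {exc.args[0]}") from None
    return min(float(r_c), float(r_p))


def _labels_to_onehot(labels: Sequence[DiagnosisClass]) -> np.ndarray:
    out = np.zeros((len(labels), 3))
    for i, lab in enumerate(labels):
        out[i, lab.severity] = 1.0
    return out


def predict_saccade_labels(
    model: TrainedModel | CNNLSTM, saccades: Sequence[Saccade]
) -> list[DiagnosisClass]:
    """Argmax class per saccade; exact probability ties break toward the
    severer class (S > P > C)."""
    net = model.model if isinstance(model, TrainedModel) else model
    if not saccades:
        return []
    X = np.stack([s.samples for s in saccades])
    probs = net.predict_proba(X)
    out: list[DiagnosisClass] = []
    for row in probs:
        best = row.max()
        # scan severest-first so ties resolve to the severer class
        for cls in sorted(_LABELS, key=lambda c: -c.severity):
            if row[cls.severity] == best:
                out.append(cls)
                break
    return out


def _validation_scores(
    net: CNNLSTM, val_dataset: SaccadeDataset
) -> tuple[dict[DiagnosisClass, float], float, float]:
    """Register-level recalls, macro recall and register accuracy on the
    validation set (original diagnoses, never relabeled)."""
    sacc_by_reg = {r.id: val_dataset.saccades_of(r.id) for r in val_dataset.registers}
    true_regs = [r.diagnosis for r in val_dataset.registers]
    pred_regs = []
    for r in val_dataset.registers:
        labels = predict_saccade_labels(net, sacc_by_reg[r.id])
        pred_regs.append(classify_register(labels))
    cm = confusion_matrix(true_regs, pred_regs, level="register")
    metrics = class_metrics(cm)
    return metrics.recall, metrics.macro_recall, cm.accuracy


def train_with_selection(
    model: CNNLSTM,
    train_saccades: Sequence[Saccade],
    val_dataset: SaccadeDataset,
    t_config: TrainingConfig = TrainingConfig(),
) -> TrainedModel:
    """Mini-batch cross-entropy training with per-epoch checkpointing.

    Training targets are the saccades' ``working_label``; validation uses
    the registers' original diagnoses.  Raises if a diagnosis class has no
    validation register (its recall would be undefined).
    """
    if not train_saccades:
        raise ValueError("empty training set")
    present = {r.diagnosis for r in val_dataset.registers}
    missing = [c.value for c in CLASSES if c not in present]
    if missing:
        raise ValueError(f"validation set lacks registers of class(es) {missing}")

    X = np.stack([s.samples for s in train_saccades])
    Y = _labels_to_onehot([s.working_label for s in train_saccades])
    n = X.shape[0]
    rng = np.random.default_rng(t_config.seed)
    opt = Adam(model.params, lr=t_config.learning_rate)

    best_key: tuple[float, float] | None = None
    best_params = model.get_params()
    best_epoch = 0
    history: list[dict] = []
    for epoch in range(1, t_config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, t_config.batch_size):
            idx = order[start : start + t_config.batch_size]
            logits, cache = model.forward(X[idx], dropout_rng=rng)
            loss, dlogits, _ = L.softmax_crossentropy(logits, Y[idx])
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        recalls, macro_recall, accuracy = _validation_scores(model, val_dataset)
        if t_config.selection == "accuracy":
            key = (accuracy, macro_recall)
            score = accuracy
        else:
            score = compromise_score(recalls)
            key = (score, macro_recall)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss,
                "val_register_recalls": {c.value: recalls[c] for c in CLASSES},
                "val_register_accuracy": accuracy,
                "selection_score": score,
            }
        )
        if best_key is None or key > best_key:
            best_key = key
            best_params = model.get_params()
            best_epoch = epoch

    model.set_params(best_params)
    return TrainedModel(
        model=model,
        training_config=t_config,
        history=history,
        selected_epoch=best_epoch,
    )
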