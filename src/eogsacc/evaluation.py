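"""Register voting, confusion matrices, per-class metrics, run averaging.

Matrices are 3x3 with rows = true class and columns = predicted class, in
C, P, S order.  Entries may be fractional after averaging over repeated
runs; metrics after averaging are always recomputed from the mean matrix
(so a mean off-diagonal of 0.7 sick-to-presymptomatic registers lowers
the accuracy accordingly), not averaged per run.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import CLASSES, DiagnosisClass

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "EvaluationReport",
    "classify_register",
    "confusion_matrix",
    "class_metrics",
    "aggregate_runs",
    "evaluate_register_predictions",
]


@dataclass
class ConfusionMatrix:
    """3x3 matrix, rows true / columns predicted, C-P-S order."""

    matrix: np.ndarray
    level: str = "register"  # or "saccade"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("confusion-matrix entries must be non-negative")
        if self.level not in ("register", "saccade"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.total) if self.total else 0.0

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


@dataclass
class ClassMetrics:
    precision: dict[DiagnosisClass, float]
    recall: dict[DiagnosisClass, float]
    f1: dict[DiagnosisClass, float]

    @property
    def macro_precision(self) -> float:
        return float(np.mean([self.precision[c] for c in CLASSES]))

    @property
    def macro_recall(self) -> float:
        return float(np.mean([self.recall[c] for c in CLASSES]))

    @property
    def macro_f1(self) -> float:
        return float(np.mean([self.f1[c] for c in CLASSES]))


@dataclass
class EvaluationReport:
    """Saccade- and register-level evaluation of one run (or a run mean)."""

    register_cm: ConfusionMatrix
    saccade_cm: ConfusionMatrix | None = None
    threshold: float | None = None
    n_runs: int = 1
    seeds: tuple[int, ...] = ()

    @property
    def register_metrics(self) -> ClassMetrics:
        return class_metrics(self.register_cm)

    @property
    def saccade_metrics(self) -> ClassMetrics | None:
        return class_metrics(self.saccade_cm) if self.saccade_cm is not None else None

    def to_dict(self) -> dict:
        def cm_block(cm: ConfusionMatrix) -> dict:
            m = class_metrics(cm)
            return {
                "matrix": cm.matrix.tolist(),
                "accuracy": cm.accuracy,
                "precision": {c.value: m.precision[c] for c in CLASSES},
                "recall": {c.value: m.recall[c] for c in CLASSES},
                "f1": {c.value: m.f1[c] for c in CLASSES},
                "macro_precision": m.macro_precision,
                "macro_recall": m.macro_recall,
                "macro_f1": m.macro_f1,
            }

        out = {
            "threshold": self.threshold,
            "n_runs": self.n_runs,
            "seeds": list(self.seeds),
            "register": cm_block(self.register_cm),
        }
        if self.saccade_cm is not None:
            out["saccade"] = cm_block(self.saccade_cm)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def classify_register(saccade_labels: Sequence[DiagnosisClass]) -> DiagnosisClass:
    """Majority vote over the register's predicted saccade labels; count
    ties break toward the severer class (S > P > C)."""
    if not saccade_labels:
        raise ValueError("cannot classify a register with no saccades")
    counts = Counter(saccade_labels)
    best = max(counts.values())
    return max((c for c, n in counts.items() if n == best), key=lambda c: c.severity)


def confusion_matrix(
    true_labels: Sequence[DiagnosisClass],
    predicted_labels: Sequence[DiagnosisClass],
    level: str = "register",
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    m = np.zeros((3, 3))
    for t, p in zip(true_labels, predicted_labels):
        if not isinstance(t, DiagnosisClass) or not isinstance(p, DiagnosisClass):
            raise ValueError(f"labels must be DiagnosisClass, got {t!r}, {p!r}")
        m[t.severity, p.severity] += 1
    return ConfusionMatrix(m, level=level)


def class_metrics(matrix: ConfusionMatrix) -> ClassMetrics:
    """Per-class precision/recall/F1 from a (possibly fractional) matrix.

    Zero denominators yield 0 (logged) so macro averages stay defined.
    """
    m = matrix.matrix
    precision: dict[DiagnosisClass, float] = {}
    recall: dict[DiagnosisClass, float] = {}
    f1: dict[DiagnosisClass, float] = {}
    for cls in CLASSES:
        i = cls.severity
        col = m[:, i].sum()
        row = m[i, :].sum()
        if col > 0:
            precision[cls] = float(m[i, i] / col)
        else:
            logger.info("no predictions for class %s; precision set to 0", cls.value)
            precision[cls] = 0.0
        if row > 0:
            recall[cls] = float(m[i, i] / row)
        else:
            logger.info("no true items of class %s; recall set to 0", cls.value)
            recall[cls] = 0.0
        denom = precision[cls] + recall[cls]
        f1[cls] = 2.0 * precision[cls] * recall[cls] / denom if denom > 0 else 0.0
    return ClassMetrics(precision, recall, f1)


def aggregate_runs(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Element-wise mean of the confusion matrices over repeated runs.

    Metrics of the result derive from the mean matrices.  All reports
    must share the threshold and have matching levels.
    """
    if not reports:
        raise ValueError("need at least one report")
    thresholds = {r.threshold for r in reports}
    if len(thresholds) > 1:
        raise ValueError(f"cannot aggregate mixed thresholds {sorted(thresholds)}")
    has_saccade = [r.saccade_cm is not None for r in reports]
    if any(has_saccade) and not all(has_saccade):
        raise ValueError("cannot aggregate mixed report levels")
    reg_mean = np.mean([r.register_cm.matrix for r in reports], axis=0)
    sac_cm = None
    if all(has_saccade):
        sac_mean = np.mean([r.saccade_cm.matrix for r in reports], axis=0)
        sac_cm = ConfusionMatrix(sac_mean, level="saccade")
    seeds = tuple(s for r in reports for s in r.seeds)
    return EvaluationReport(
        register_cm=ConfusionMatrix(reg_mean, level="register"),
        saccade_cm=sac_cm,
        threshold=reports[0].threshold,
        n_runs=sum(r.n_runs for r in reports),
        seeds=seeds,
    )


def evaluate_register_predictions(
    register_true: Sequence[DiagnosisClass],
    register_pred: Sequence[DiagnosisClass],
    saccade_true: Sequence[DiagnosisClass] | None = None,
    saccade_pred: Sequence[DiagnosisClass] | None = None,
    threshold: float | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Bundle register-level (and optionally saccade-level) matrices."""
    reg_cm = confusion_matrix(register_true, register_pred, level="register")
    sac_cm = None
    if saccade_true is not None and saccade_pred is not None:
        sac_cm = confusion_matrix(saccade_true, saccade_pred, level="saccade")
    return EvaluationReport(
        register_cm=reg_cm,
        saccade_cm=sac_cm,
        threshold=threshold,
        n_runs=1,
        seeds=(seed,) if seed is not None else (),
    )
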