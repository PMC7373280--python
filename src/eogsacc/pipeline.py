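"""End-to-end orchestration: split, relabel, train, vote, sweep, select.

A *single run* at threshold t: train the map on the training saccades,
relabel their working labels (skipped when t = 0, the no-relabel
baseline), train the classifier with validation-recall checkpointing,
predict the test saccades and vote per register.  A *sweep* repeats this
for t in {0} U sweep_values with ``repeats`` seeded runs per threshold on
one fixed register split, and the final threshold is the one maximizing
the validation register recall compromise min(recall_C, recall_P).

Seed scheme: the split uses ``split_seed`` alone; every run derives its
seed deterministically from (root_seed, threshold-in-thousandths, repeat
index) through ``numpy.random.SeedSequence``, and the map / model /
shuffling streams are spawned from that run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import (
    CLASSES,
    DatasetSplit,
    DiagnosisClass,
    SaccadeDataset,
    split_registers,
)
from .cnn_lstm import (
    CNNLSTM,
    ModelConfig,
    TrainingConfig,
    predict_saccade_labels,
    train_with_selection,
)
from .evaluation import (
    EvaluationReport,
    aggregate_runs,
    classify_register,
    evaluate_register_predictions,
)
from .som import DEFAULT_SWEEP, RelabelSummary, relabel_training_set, train_som
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "SOMParams",
    "PipelineConfig",
    "SweepResult",
    "derive_seed",
    "run_single",
    "run_threshold_sweep",
    "select_threshold",
    "run_full_pipeline",
]


def derive_seed(root_seed: int, *keys: int) -> int:
    """Deterministic child seed from a root seed and integer keys."""
    ss = np.random.SeedSequence([int(root_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class SOMParams:
    width: int = 8
    height: int = 8
    epochs: int = 10
    learning_rate: float = 0.5
    radius: float | None = None


@dataclass
class PipelineConfig:
    data_path: str | None = None
    generator: GeneratorConfig | None = None
    split_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    split_seed: int = 0
    som: SOMParams = field(default_factory=SOMParams)
    sweep_values: tuple[float, ...] = DEFAULT_SWEEP
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    repeats: int = 10
    root_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if any(v <= 0 for v in self.sweep_values):
            raise ValueError("sweep values must be positive")
        if self.data_path is None and self.generator is None:
            raise ValueError("need either data_path or a generator config")


@dataclass
class SweepResult:
    """Aggregated reports per threshold (0 = no-relabel baseline)."""

    entries: dict[float, dict] = field(default_factory=dict)
    # entries[theta] = {"val": EvaluationReport, "test": EvaluationReport,
    #                   "relabel_summaries": list[RelabelSummary]}

    @property
    def thresholds(self) -> list[float]:
        return sorted(self.entries)


def _load_dataset(config: PipelineConfig) -> SaccadeDataset:
    if config.data_path is not None:
        from .core_data import read_saccade_table

        return read_saccade_table(config.data_path)
    return generate_dataset(config.generator)


def _labels_checksum(dataset: SaccadeDataset, register_ids: Sequence[str]) -> str:
    h = hashlib.sha256()
    for rid in sorted(register_ids):
        for s in dataset.saccades_of(rid):
            h.update(f"{s.id}:{s.given_label.value};".encode())
    return h.hexdigest()


def run_single(
    config: PipelineConfig,
    threshold: float,
    run_seed: int,
    dataset: SaccadeDataset | None = None,
    split: DatasetSplit | None = None,
    som_seed: int | None = None,
) -> tuple[EvaluationReport, EvaluationReport, RelabelSummary | None]:
    """One relabel-train-evaluate run. threshold = 0 skips relabeling.

    ``som_seed`` lets a sweep share one map per repeat across thresholds
    (the map is created once, before the threshold loop); by default it is
    derived from ``run_seed``.  Returns (validation report, test report,
    relabel summary or None).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if dataset is None:
        dataset = _load_dataset(config)
    if split is None:
        split = split_registers(dataset, config.split_fractions, config.split_seed)

    train_ds = dataset.subset(split.train_register_ids, "train")
    val_ds = dataset.subset(split.val_register_ids, "validation")
    test_ds = dataset.subset(split.test_register_ids, "test")
    val_sum = _labels_checksum(dataset, split.val_register_ids)
    test_sum = _labels_checksum(dataset, split.test_register_ids)

    train_saccades = list(train_ds.saccades)
    summary: RelabelSummary | None = None
    if threshold > 0:
        if som_seed is None:
            som_seed = derive_seed(run_seed, 1)
        grid = train_som(
            train_saccades,
            width=config.som.width,
            height=config.som.height,
            epochs=config.som.epochs,
            learning_rate=config.som.learning_rate,
            radius=config.som.radius,
            seed=som_seed,
        )
        train_saccades, summary = relabel_training_set(grid, train_saccades, threshold)
        logger.info(
            "threshold %.2f: relabeled %d of %d training saccades",
            threshold, summary.n_changed, len(train_saccades),
        )

    model = CNNLSTM(config.model, seed=derive_seed(run_seed, 2))
    t_config = dataclasses.replace(config.training, seed=derive_seed(run_seed, 3))
    trained = train_with_selection(model, train_saccades, val_ds, t_config)

    def _evaluate(ds: SaccadeDataset) -> EvaluationReport:
        sac_true: list[DiagnosisClass] = []
        sac_pred: list[DiagnosisClass] = []
        reg_true: list[DiagnosisClass] = []
        reg_pred: list[DiagnosisClass] = []
        for reg in ds.registers:
            sacs = ds.saccades_of(reg.id)
            preds = predict_saccade_labels(trained, sacs)
            sac_true += [s.given_label for s in sacs]
            sac_pred += preds
            reg_true.append(reg.diagnosis)
            reg_pred.append(classify_register(preds))
        return evaluate_register_predictions(
            reg_true, reg_pred, sac_true, sac_pred,
            threshold=threshold, seed=run_seed,
        )

    val_report = _evaluate(val_ds)
    test_report = _evaluate(test_ds)

    # relabeling must never leak into validation/test given labels
    assert _labels_checksum(dataset, split.val_register_ids) == val_sum
    assert _labels_checksum(dataset, split.test_register_ids) == test_sum
    return val_report, test_report, summary


def run_threshold_sweep(
    config: PipelineConfig,
    dataset: SaccadeDataset | None = None,
    split: DatasetSplit | None = None,
) -> SweepResult:
    """Baseline plus every sweep threshold, ``repeats`` runs each, on one
    shared split."""
    if dataset is None:
        dataset = _load_dataset(config)
    if split is None:
        split = split_registers(dataset, config.split_fractions, config.split_seed)
    result = SweepResult()
    for theta in [0.0, *config.sweep_values]:
        val_reports: list[EvaluationReport] = []
        test_reports: list[EvaluationReport] = []
        summaries: list[RelabelSummary] = []
        for rep in range(config.repeats):
            run_seed = derive_seed(config.root_seed, int(round(theta * 1000)), rep)
            # one map per repeat, shared across all thresholds: the map is
            # created once, before the threshold loop
            som_seed = derive_seed(config.root_seed, 999_983, rep)
            t0 = time.time()
            val_r, test_r, summ = run_single(
                config, theta, run_seed, dataset, split, som_seed=som_seed
            )
            logger.info(
                "theta=%.2f repeat=%d done in %.1fs (test register acc %.3f)",
                theta, rep, time.time() - t0, test_r.register_cm.accuracy,
            )
            val_reports.append(val_r)
            test_reports.append(test_r)
            if summ is not None:
                summaries.append(summ)
        result.entries[theta] = {
            "val": aggregate_runs(val_reports),
            "test": aggregate_runs(test_reports),
            "relabel_summaries": summaries,
        }
    return result


def select_threshold(sweep: SweepResult) -> float:
    """Threshold maximizing the aggregated validation register recall
    compromise; ties -> higher macro recall, then smaller threshold."""
    candidates = [t for t in sweep.thresholds if t > 0]
    if not candidates:
        raise ValueError("sweep contains no non-baseline thresholds")
    best_theta = None
    best_key: tuple[float, float, float] | None = None
    for theta in candidates:
        metrics = sweep.entries[theta]["val"].register_metrics
        score = min(metrics.recall[DiagnosisClass.C], metrics.recall[DiagnosisClass.P])
        key = (score, metrics.macro_recall, -theta)
        if best_key is None or key > best_key:
            best_key = key
            best_theta = theta
    return float(best_theta)


def run_full_pipeline(config: PipelineConfig) -> tuple[float, EvaluationReport, SweepResult]:
    """Sweep, select, and report the selected threshold's test evaluation.

    When ``config.out_dir`` is set, writes a run directory with the config
    snapshot, per-threshold reports, relabel summaries and plots.
    """
    dataset = _load_dataset(config)
    split = split_registers(dataset, config.split_fractions, config.split_seed)
    sweep = run_threshold_sweep(config, dataset, split)
    selected = select_threshold(sweep)
    final = sweep.entries[selected]["test"]

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_artifacts(out, config, split, sweep, selected, final)
    return selected, final, sweep


def _config_snapshot(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, DiagnosisClass):
            return obj.value
        if isinstance(obj, dict):
            return {getattr(k, "value", k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return {
        "data_path": config.data_path,
        "generator": enc(config.generator) if config.generator else None,
        "split_fractions": list(config.split_fractions),
        "split_seed": config.split_seed,
        "som": enc(config.som),
        "sweep_values": list(config.sweep_values),
        "model": enc(config.model),
        "training": enc(config.training),
        "repeats": config.repeats,
        "root_seed": config.root_seed,
    }


def _write_artifacts(
    out: Path,
    config: PipelineConfig,
    split: DatasetSplit,
    sweep: SweepResult,
    selected: float,
    final: EvaluationReport,
) -> None:
    (out / "config.json").write_text(json.dumps(_config_snapshot(config), indent=2))
    (out / "split.json").write_text(
        json.dumps(
            {
                "train": list(split.train_register_ids),
                "val": list(split.val_register_ids),
                "test": list(split.test_register_ids),
                "seed": split.seed,
            },
            indent=2,
        )
    )
    sweep_block = {}
    relabel_rows = []
    for theta, entry in sweep.entries.items():
        sweep_block[str(theta)] = {
            "val": entry["val"].to_dict(),
            "test": entry["test"].to_dict(),
        }
        for summ in entry["relabel_summaries"]:
            relabel_rows += summ.to_rows()
    (out / "sweep.json").write_text(json.dumps(sweep_block, indent=2, sort_keys=True))
    (out / "selected.json").write_text(
        json.dumps({"threshold": selected, "test": final.to_dict()}, indent=2)
    )
    if relabel_rows:
        import pandas as pd

        pd.DataFrame(relabel_rows).to_csv(out / "relabel_summary.csv", index=False)
    try:
        _write_plots(out, sweep, selected)
    except Exception as exc:  # plotting is best-effort
        logger.warning("plot generation failed: %s", exc)


def _write_plots(out: Path, sweep: SweepResult, selected: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thetas = sweep.thresholds
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, metric in zip(axes, ("recall", "precision", "f1")):
        for cls in CLASSES:
            ys = [
                getattr(sweep.entries[t]["val"].register_metrics, metric)[cls]
                for t in thetas
            ]
            ax.plot(thetas, ys, marker="o", label=cls.value)
        ax.set_xlabel("threshold (0 = no relabeling)")
        ax.set_title(f"validation register {metric}")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "threshold_metrics.png", dpi=120)
    plt.close(fig)

    cm = sweep.entries[selected]["test"].register_cm.matrix
    fig, ax = plt.subplots(figsize=(3.5, 3))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, f"{cm[i, j]:.1f}", ha="center", va="center")
    ax.set_xticks(range(3), [c.value for c in CLASSES])
    ax.set_yticks(range(3), [c.value for c in CLASSES])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"test registers, threshold {selected:g}")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(out / "test_confusion.png", dpi=120)
    plt.close(fig)
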