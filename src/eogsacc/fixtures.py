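"""Reference fixture configurations used by the acceptance checks.

These freeze the synthetic-data and pipeline settings under which the
method's qualitative behavior (baseline misses every presymptomatic
register; the relabeled pipeline recovers at least half) is demonstrated
and regression-tested.  Kept inside the package so tests and reporting
scripts share one definition.
"""

from __future__ import annotations

from .cnn_lstm import ModelConfig, TrainingConfig
from .core_data import DiagnosisClass
from .pipeline import PipelineConfig, SOMParams
from .synthetic import GeneratorConfig, ShapeParams

__all__ = [
    "overlapping_class_shapes",
    "label_recovery_generator",
    "end_to_end_config",
    "END_TO_END_SEED",
]

#: Root seed of the frozen end-to-end demonstration.
END_TO_END_SEED = 8


def overlapping_class_shapes() -> dict[DiagnosisClass, ShapeParams]:
    """Class shapes with deliberate control/presymptomatic overlap.

    The presymptomatic rise time sits close to the control one and the
    noise floor is raised, so the two classes blend at the cell level —
    the regime the relabeling threshold is designed for.
    """
    return {
        DiagnosisClass.C: ShapeParams(rise_tau=2.5, noise_sd=1.5, baseline_sd=0.5),
        DiagnosisClass.P: ShapeParams(rise_tau=4.0, noise_sd=1.5, baseline_sd=0.5),
        DiagnosisClass.S: ShapeParams(
            rise_tau=10.0, dysmetria_fraction=0.15, noise_sd=1.5, baseline_sd=0.5
        ),
    }


def label_recovery_generator(seed: int, contamination: float = 0.4) -> GeneratorConfig:
    """Dataset settings for the true-shape label-recovery check (default
    well-separated shapes, larger registers for stable cell counts)."""
    return GeneratorConfig(
        contamination=contamination,
        saccades_per_register=(20, 30),
        seed=seed,
    )


def end_to_end_config(seed: int = END_TO_END_SEED) -> PipelineConfig:
    """Scaled-down full-pipeline configuration: 30 registers, a small
    model, at most 15 epochs, 2 repeats per threshold."""
    return PipelineConfig(
        generator=GeneratorConfig(
            registers_per_class=(14, 8, 8),
            saccades_per_register=(16, 24),
            contamination=0.6,
            class_shapes=overlapping_class_shapes(),
            seed=seed,
        ),
        split_seed=seed,
        som=SOMParams(width=5, height=5),
        model=ModelConfig(conv_filters=16, lstm_units=16, dropout_rate=0.1),
        training=TrainingConfig(max_epochs=15, batch_size=16, learning_rate=1e-2),
        repeats=2,
        root_seed=seed,
    )
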