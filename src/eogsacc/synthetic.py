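"""Synthetic saccade-register generator.

Produces datasets with the bag-level label-noise structure the relabeling
method targets: control (C) registers hold only control-shaped saccades,
sick (S) registers only sick-shaped ones, while each presymptomatic (P)
register mixes a fraction ``contamination`` of control-shaped saccades
with genuinely slowed, presymptomatic-shaped ones.  Every saccade's
``given_label`` is its register's diagnosis; the shape actually drawn is
retained in ``true_shape_label`` so recovery can be scored.

Waveforms are logistic steps: slower rise (larger tau) for affected
classes, plus an optional delayed secondary step (dysmetria) for the sick
class.  All randomness flows from one root seed through
``numpy.random.SeedSequence`` spawn keys (register index, saccade index),
making generation a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_data import (
    ALLOWED_ANGLES,
    WINDOW_LENGTH,
    CLASSES,
    DiagnosisClass,
    Register,
    Saccade,
    SaccadeDataset,
)
from .preprocess import normalize_amplitude, normalize_direction, PreprocessConfig

__all__ = [
    "ShapeParams",
    "GeneratorConfig",
    "DEFAULT_CLASS_SHAPES",
    "DYSMETRIA_DELAY",
    "generate_saccade_waveform",
    "generate_dataset",
    "FixationSpec",
    "SaccadePlanSpec",
    "generate_raw_trace",
]

#: Delay (samples) of the secondary dysmetric step.
DYSMETRIA_DELAY = 20


@dataclass(frozen=True)
class ShapeParams:
    """Waveform shape for one diagnosis class.

    ``rise_tau`` is the logistic time constant in samples;
    ``dysmetria_fraction`` the amplitude of a delayed secondary step as a
    fraction of the main amplitude.
    """

    rise_tau: float
    dysmetria_fraction: float = 0.0
    noise_sd: float = 0.5
    baseline_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.rise_tau <= 0:
            raise ValueError(f"rise_tau must be > 0, got {self.rise_tau}")
        if not 0 <= self.dysmetria_fraction < 1:
            raise ValueError("dysmetria_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


#: Default per-class shapes: progressively slower rise, dysmetria for S.
DEFAULT_CLASS_SHAPES: dict[DiagnosisClass, ShapeParams] = {
    DiagnosisClass.C: ShapeParams(rise_tau=2.5),
    DiagnosisClass.P: ShapeParams(rise_tau=5.0),
    DiagnosisClass.S: ShapeParams(rise_tau=10.0, dysmetria_fraction=0.15),
}


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate_dataset`.

    ``registers_per_class`` is (C, P, S).  The default class imbalance
    mirrors a realistic clinic mix where controls dominate.
    ``contamination`` is the fraction of control-shaped saccades inside
    each presymptomatic register.
    """

    registers_per_class: tuple[int, int, int] = (14, 6, 10)
    saccades_per_register: tuple[int, int] = (12, 20)
    contamination: float = 0.6
    class_shapes: Mapping[DiagnosisClass, ShapeParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SHAPES)
    )
    angles: Mapping[int, float] = field(
        default_factory=lambda: {a: 1.0 for a in ALLOWED_ANGLES}
    )
    rtl_probability: float = 0.5
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contamination <= 1:
            raise ValueError("contamination must be in [0, 1]")
        if any(n <= 0 for n in self.registers_per_class):
            raise ValueError("registers_per_class entries must be positive")
        if not self.angles:
            raise ValueError("need at least one stimulus angle")
        for a in self.angles:
            if a not in ALLOWED_ANGLES:
                raise ValueError(f"angle {a} not in {ALLOWED_ANGLES}")
        lo, hi = self.saccades_per_register
        if lo < 1 or hi < lo:
            raise ValueError("saccades_per_register must be a valid range")


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))


def generate_saccade_waveform(
    shape: ShapeParams,
    angle: float,
    direction: int = 1,
    t0: int = WINDOW_LENGTH // 2,
    length: int = WINDOW_LENGTH,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One noisy logistic-step saccade of target amplitude ``angle``.

    s(t) = direction * A * [logistic((t-t0)/tau)
                            + dysmetria * logistic((t-t0-delay)/tau)]
           + baseline + noise(t)
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= t0 < length:
        raise ValueError(f"t0={t0} outside [0, {length})")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(length, dtype=np.float64)
    step = _logistic((t - t0) / shape.rise_tau)
    if shape.dysmetria_fraction > 0:
        step = step + shape.dysmetria_fraction * _logistic(
            (t - t0 - DYSMETRIA_DELAY) / shape.rise_tau
        )
    baseline = rng.normal(0.0, shape.baseline_sd) if shape.baseline_sd > 0 else 0.0
    noise = rng.normal(0.0, shape.noise_sd, size=length) if shape.noise_sd > 0 else 0.0
    return direction * float(angle) * step + baseline + noise


def _p_register_shape_counts(n: int, contamination: float) -> tuple[int, int]:
    """(control-shaped, presymptomatic-shaped) counts for a P register of
    n saccades; at least one presymptomatic-shaped saccade always."""
    n_c = int(np.floor(contamination * n + 0.5))
    n_c = min(n_c, n - 1)  # guard: >= 1 genuinely slowed saccade
    return n_c, n - n_c


def generate_dataset(config: GeneratorConfig) -> SaccadeDataset:
    """Generate a full labeled dataset, reproducible from ``config.seed``."""
    angles = sorted(config.angles)
    weights = np.array([config.angles[a] for a in angles], dtype=float)
    weights = weights / weights.sum()
    pre = PreprocessConfig()

    registers: list[Register] = []
    saccades: list[Saccade] = []
    reg_index = 0
    for cls, n_regs in zip(CLASSES, config.registers_per_class):
        for k in range(n_regs):
            reg_id = f"{cls.value}{k:02d}"
            # deterministic substream per register
            reg_ss = np.random.SeedSequence([config.seed, reg_index])
            rng = np.random.default_rng(reg_ss)
            n_sacc = int(rng.integers(config.saccades_per_register[0],
                                      config.saccades_per_register[1] + 1))
            if cls is DiagnosisClass.P:
                n_c, n_p = _p_register_shape_counts(n_sacc, config.contamination)
                shape_labels = [DiagnosisClass.C] * n_c + [DiagnosisClass.P] * n_p
                rng.shuffle(shape_labels)
            else:
                shape_labels = [cls] * n_sacc
            sac_ids = []
            for j, shape_cls in enumerate(shape_labels):
                sac_rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, reg_index, j])
                )
                angle = int(sac_rng.choice(angles, p=weights))
                direction = -1 if sac_rng.random() < config.rtl_probability else 1
                wave = generate_saccade_waveform(
                    config.class_shapes[shape_cls], angle, direction,
                    seed=sac_rng,
                )
                if config.normalize:
                    wave = normalize_direction(normalize_amplitude(wave, angle, pre))
                sid = f"{reg_id}_s{j:03d}"
                sac_ids.append(sid)
                saccades.append(
                    Saccade(
                        id=sid,
                        register_id=reg_id,
                        stimulus_angle=angle,
                        samples=wave,
                        given_label=cls,
                        true_shape_label=shape_cls,
                    )
                )
            registers.append(Register(reg_id, cls, sac_ids))
            reg_index += 1
    provenance = (
        f"synthetic(seed={config.seed}, registers={config.registers_per_class}, "
        f"contamination={config.contamination})"
    )
    return SaccadeDataset(registers, saccades, provenance)


# ---------------------------------------------------------------------------
# Raw traces (segmentation fixtures)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixationSpec:
    """A constant-gaze segment of ``duration`` samples."""

    duration: int


@dataclass(frozen=True)
class SaccadePlanSpec:
    """A planned saccade: logistic transition over ``duration`` samples."""

    shape: ShapeParams
    angle: float
    direction: int = 1
    duration: int = 40


def generate_raw_trace(
    plan: Sequence[FixationSpec | SaccadePlanSpec],
    sampling_rate: float = 200.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Concatenate fixations and saccade transitions into one trace.

    Returns the trace and the ground-truth (onset, offset) intervals of
    the planned saccades, 0-based half-open.
    """
    if not plan:
        raise ValueError("plan must not be empty")
    rng = np.random.default_rng(seed)
    pieces: list[np.ndarray] = []
    intervals: list[tuple[int, int]] = []
    level = 0.0
    pos = 0
    for item in plan:
        if isinstance(item, FixationSpec):
            if item.duration < 0:
                raise ValueError("fixation duration must be >= 0")
            pieces.append(np.full(item.duration, level))
            pos += item.duration
        elif isinstance(item, SaccadePlanSpec):
            d = item.duration
            if d < 1:
                raise ValueError("saccade duration must be >= 1")
            t = np.arange(d, dtype=np.float64)
            step = _logistic((t - d / 2.0) / item.shape.rise_tau)
            if item.shape.dysmetria_fraction > 0:
                step = step + item.shape.dysmetria_fraction * _logistic(
                    (t - d / 2.0 - DYSMETRIA_DELAY) / item.shape.rise_tau
                )
            jump = item.direction * item.angle
            pieces.append(level + jump * step)
            intervals.append((pos, pos + d))
            level = level + jump * (1.0 + item.shape.dysmetria_fraction)
            pos += d
        else:
            raise TypeError(f"unknown plan entry {item!r}")
    trace = np.concatenate(pieces) if pieces else np.zeros(0)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return trace, intervals
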