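"""Saccade segmentation from raw traces and window normalization.

Segmentation clusters per-sample absolute velocities into two groups with
k-means; the high-velocity cluster marks saccadic samples.  Windows of
fixed length are cut from each detected saccade's center, scaled so every
stimulus angle maps to the same nominal amplitude, and flipped so all
saccades read left-to-right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core_data import WINDOW_LENGTH

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "compute_velocity",
    "segment_saccades",
    "extract_window",
    "normalize_amplitude",
    "normalize_direction",
]


@dataclass(frozen=True)
class PreprocessConfig:
    window_length: int = WINDOW_LENGTH
    target_amplitude: float = 30.0
    sampling_rate: float = 200.0
    min_saccade_duration: int = 5
    merge_gap: int = 3
    kmeans_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.target_amplitude <= 0:
            raise ValueError("target_amplitude must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


def compute_velocity(trace: np.ndarray, sampling_rate: float = 200.0) -> np.ndarray:
    """First difference scaled to degrees/second; length = len(trace) - 1."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.shape[0] < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    return np.diff(trace) * float(sampling_rate)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector, 0-based half-open."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def segment_saccades(
    trace: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> list[tuple[int, int]]:
    """Detect saccade intervals on one horizontal trace.

    2-cluster k-means on |velocity|; the larger-centroid cluster marks
    saccadic velocity samples.  Runs separated by at most ``merge_gap``
    samples are merged; runs shorter than ``min_saccade_duration`` are
    dropped.  Intervals are in trace-sample coordinates (a saccadic
    velocity sample i spans trace samples i and i+1).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.shape[0] <= config.window_length:
        raise ValueError(
            f"trace length {trace.shape[0]} must exceed window_length "
            f"{config.window_length}"
        )
    speed = np.abs(compute_velocity(trace, config.sampling_rate))
    if np.ptp(speed) == 0.0:
        logger.warning("degenerate trace (constant velocity); no saccades found")
        return []
    km = KMeans(n_clusters=2, n_init=10, random_state=config.kmeans_seed)
    labels = km.fit_predict(speed.reshape(-1, 1))
    fast = int(np.argmax(km.cluster_centers_.ravel()))
    mask = labels == fast
    runs = _runs(mask)
    # merge runs separated by small gaps
    merged: list[tuple[int, int]] = []
    for on, off in runs:
        if merged and on - merged[-1][1] <= config.merge_gap:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    # velocity index run [i, j) covers trace samples [i, j+1)
    out = [
        (on, off + 1)
        for on, off in merged
        if (off + 1 - on) >= config.min_saccade_duration
    ]
    return out


def extract_window(
    trace: np.ndarray,
    interval: tuple[int, int],
    config: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray | None:
    """Window of ``window_length`` samples centered on the interval midpoint.

    Returns None (and logs) when the window would exceed the trace.
    """
    trace = np.asarray(trace, dtype=np.float64)
    onset, offset = interval
    if not (0 <= onset < offset <= trace.shape[0]):
        raise ValueError(f"interval {interval} outside trace of length {trace.shape[0]}")
    center = (onset + offset) // 2
    start = center - config.window_length // 2
    end = start + config.window_length
    if start < 0 or end > trace.shape[0]:
        logger.info("window for interval %s out of bounds; discarded", interval)
        return None
    return trace[start:end].copy()


def normalize_amplitude(
    samples: np.ndarray, angle: float, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Scale by target_amplitude/angle so all stimuli share one amplitude."""
    if angle <= 0:
        raise ValueError(f"angle must be > 0, got {angle}")
    return np.asarray(samples, dtype=np.float64) * (config.target_amplitude / float(angle))


def normalize_direction(samples: np.ndarray) -> np.ndarray:
    """Flip right-to-left saccades so every window rises.

    Direction is judged by quarter means: if mean(last quarter) <
    mean(first quarter) the window is negated.  Idempotent; exact ties
    leave the window unchanged.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.shape[0] < 8:
        raise ValueError("need at least 8 samples to judge direction")
    q = x.shape[0] // 4
    d = x[-q:].mean() - x[:q].mean()
    return -x if d < 0 else x.copy()
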