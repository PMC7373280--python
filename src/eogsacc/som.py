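"""Self-organizing map training and label correction of training saccades.

The map is a rectangular grid of weight vectors in saccade space, trained
by the classic sequential rule: for each presented sample the
Euclidean-nearest cell (best matching unit, BMU) wins and every cell
moves toward the sample in proportion to a Gaussian function of its grid
distance to the winner; learning rate and neighborhood radius decay
linearly to a small floor.

Relabeling then works per cell.  For each training saccade, the labels of
all training saccades sharing its BMU are counted as (nC, nP, nS) and the
decision tree is:

* strict sick plurality (nS > nC and nS > nP)  ->  S
* no presymptomatic present (nP == 0)          ->  C
* nC / nP below the threshold                  ->  P
* otherwise                                    ->  C

so the control label must outnumber the presymptomatic one by at least
the threshold ratio before a mixed cell is still called control.  Only
``working_label`` is touched; given labels are immutable.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_data import CLASSES, WINDOW_LENGTH, DiagnosisClass, Saccade

__all__ = [
    "SOMGrid",
    "CellCounts",
    "RelabelConfig",
    "RelabelSummary",
    "train_som",
    "assign_bmu",
    "assign_bmus",
    "compute_cell_counts",
    "relabel_saccade",
    "relabel_training_set",
    "quantization_error",
    "save_som",
    "load_som",
]

DEFAULT_SWEEP = (2.0, 3.0, 4.0, 4.5)


@dataclass
class SOMGrid:
    """Trained map: ``weights`` has shape (height, width, dim)."""

    width: int
    height: int
    weights: np.ndarray
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape[:2] != (self.height, self.width):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match grid "
                f"{self.height}x{self.width}"
            )

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    @property
    def flat_weights(self) -> np.ndarray:
        return self.weights.reshape(-1, self.dim)


@dataclass
class CellCounts:
    """Per-cell (nC, nP, nS) label counts; shape (height, width, 3)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 3:
            raise ValueError("counts must have shape (height, width, 3)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def cell(self, row: int, col: int) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.counts[row, col])

    def class_totals(self) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.counts.sum(axis=(0, 1)))


@dataclass(frozen=True)
class RelabelConfig:
    threshold: float = 4.0
    sweep_values: tuple[float, ...] = DEFAULT_SWEEP

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class RelabelSummary:
    """Transition tallies for one relabeling pass at one threshold."""

    threshold: float
    transitions: Counter = field(default_factory=Counter)

    def count(self, src: DiagnosisClass, dst: DiagnosisClass) -> int:
        return int(self.transitions.get((src, dst), 0))

    @property
    def n_changed(self) -> int:
        return sum(v for (a, b), v in self.transitions.items() if a is not b)

    def relabeled_to(self, dst: DiagnosisClass) -> int:
        return sum(v for (a, b), v in self.transitions.items() if b is dst and a is not dst)

    def to_rows(self) -> list[dict]:
        return [
            {"threshold": self.threshold, "from": a.value, "to": b.value, "count": int(v)}
            for (a, b), v in sorted(
                self.transitions.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ]


def _as_matrix(saccades: Iterable[Saccade] | np.ndarray) -> np.ndarray:
    if isinstance(saccades, np.ndarray):
        X = np.asarray(saccades, dtype=np.float64)
    else:
        X = np.stack([s.samples for s in saccades]).astype(np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D sample matrix")
    return X


def train_som(
    saccades: Iterable[Saccade] | np.ndarray,
    width: int = 8,
    height: int = 8,
    epochs: int = 10,
    learning_rate: float = 0.5,
    radius: float | None = None,
    seed: int = 0,
) -> SOMGrid:
    """Sequential SOM training, deterministic given the seed.

    Weights are initialized from randomly drawn training samples.
    Learning rate and radius decay linearly to 1% of their initial value
    over the full presentation schedule (epochs x n samples).
    """
    X = _as_matrix(saccades)
    n, dim = X.shape
    if n < 1:
        raise ValueError("need at least one training saccade")
    if width < 1 or height < 1 or epochs < 1 or learning_rate <= 0:
        raise ValueError("grid dims, epochs and learning_rate must be positive")
    if radius is None:
        radius = max(width, height) / 2.0
    if radius <= 0:
        raise ValueError("radius must be positive")

    rng = np.random.default_rng(seed)
    n_cells = width * height
    init_idx = rng.integers(0, n, size=n_cells)
    W = X[init_idx].reshape(height, width, dim).copy()

    rows, cols = np.indices((height, width))
    grid_pos = np.stack([rows, cols], axis=-1).astype(np.float64)  # (H, W, 2)

    total = epochs * n
    lr_floor = 0.01 * learning_rate
    rad_floor = max(0.01 * radius, 1e-3)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total - 1, 1)
            lr = learning_rate + (lr_floor - learning_rate) * frac
            sigma = radius + (rad_floor - radius) * frac
            x = X[i]
            d2 = ((W - x) ** 2).sum(axis=2)
            bmu = np.unravel_index(int(np.argmin(d2)), (height, width))
            gd2 = ((grid_pos - np.array(bmu, dtype=np.float64)) ** 2).sum(axis=2)
            h = np.exp(-gd2 / (2.0 * sigma * sigma))
            W += (lr * h)[:, :, None] * (x - W)
            step += 1

    return SOMGrid(
        width=width,
        height=height,
        weights=W,
        hyperparams={
            "learning_rate": learning_rate,
            "radius": radius,
            "epochs": epochs,
            "seed": int(seed),
        },
    )


def assign_bmu(grid: SOMGrid, samples: np.ndarray) -> tuple[int, int]:
    """Best matching unit of one sample; ties -> smallest row-major index."""
    x = np.asarray(samples, dtype=np.float64)
    if x.shape != (grid.dim,):
        raise ValueError(f"sample must have length {grid.dim}, got {x.shape}")
    d2 = ((grid.flat_weights - x) ** 2).sum(axis=1)
    flat = int(np.argmin(d2))  # argmin returns the first minimum: row-major tie-break
    return flat // grid.width, flat % grid.width


def assign_bmus(grid: SOMGrid, X: np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup; returns an (n, 2) array of (row, col)."""
    X = _as_matrix(X)
    W = grid.flat_weights
    d2 = (
        (X ** 2).sum(axis=1, keepdims=True)
        - 2.0 * X @ W.T
        + (W ** 2).sum(axis=1)[None, :]
    )
    flat = np.argmin(d2, axis=1)
    return np.stack([flat // grid.width, flat % grid.width], axis=1)


def compute_cell_counts(grid: SOMGrid, saccades: Sequence[Saccade]) -> CellCounts:
    """Count given labels of the saccades mapped to each cell (each
    saccade contributes to its own cell's counts)."""
    counts = np.zeros((grid.height, grid.width, 3), dtype=np.int64)
    if saccades:
        X = np.stack([s.samples for s in saccades])
        bmus = assign_bmus(grid, X)
        for s, (r, c) in zip(saccades, bmus):
            counts[r, c, s.given_label.severity] += 1
    return CellCounts(counts)


def relabel_saccade(counts: tuple[int, int, int], threshold: float) -> DiagnosisClass:
    """Decide a cell's label from its (nC, nP, nS) counts.

    S on strict sick plurality; C when no presymptomatic label is
    present; otherwise P iff nC/nP is below the threshold, else C.
    """
    n_c, n_p, n_s = (int(v) for v in counts)
    if n_c < 0 or n_p < 0 or n_s < 0:
        raise ValueError("counts must be non-negative")
    if n_c + n_p + n_s < 1:
        raise ValueError("cell has no saccades")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if n_s > n_c and n_s > n_p:
        return DiagnosisClass.S
    if n_p == 0:
        return DiagnosisClass.C
    if n_c / n_p < threshold:
        return DiagnosisClass.P
    return DiagnosisClass.C


def relabel_training_set(
    grid: SOMGrid,
    saccades: Sequence[Saccade],
    threshold: float,
) -> tuple[list[Saccade], RelabelSummary]:
    """Set every training saccade's working label from its BMU cell.

    Returns fresh ``Saccade`` copies (inputs are not mutated) plus a
    summary of given-label -> new-label transitions.
    """
    counts = compute_cell_counts(grid, saccades)
    summary = RelabelSummary(threshold=float(threshold))
    if not saccades:
        return [], summary
    X = np.stack([s.samples for s in saccades])
    bmus = assign_bmus(grid, X)
    out: list[Saccade] = []
    for s, (r, c) in zip(saccades, bmus):
        new_label = relabel_saccade(counts.cell(r, c), threshold)
        summary.transitions[(s.given_label, new_label)] += 1
        out.append(replace(s, samples=s.samples.copy(), working_label=new_label))
    return out, summary


def quantization_error(grid: SOMGrid, saccades: Iterable[Saccade] | np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU weight."""
    X = _as_matrix(saccades)
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    bmus = assign_bmus(grid, X)
    W = grid.weights[bmus[:, 0], bmus[:, 1]]
    return float(np.linalg.norm(X - W, axis=1).mean())


def save_som(grid: SOMGrid, path: str | Path) -> None:
    """Persist as JSON: dims + hyperparams + weight list (portable text)."""
    payload = {
        "width": grid.width,
        "height": grid.height,
        "dim": grid.dim,
        "hyperparams": grid.hyperparams,
        "weights": grid.flat_weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_som(path: str | Path) -> SOMGrid:
    payload = json.loads(Path(path).read_text())
    W = np.asarray(payload["weights"], dtype=np.float64).reshape(
        payload["height"], payload["width"], payload["dim"]
    )
    return SOMGrid(payload["width"], payload["height"], W, payload.get("hyperparams", {}))
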