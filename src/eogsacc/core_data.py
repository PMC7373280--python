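"""Domain types, saccade-table I/O and register-stratified splitting.

A *saccade* is a 192-sample window of horizontal eye position (degrees).
A *register* groups all saccades recorded from one subject and carries a
single diagnosis label; every saccade inherits that label as its
``given_label``.  The mutable ``working_label`` is the one training
consumes and is the only field the relabeling stage may change.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_LENGTH = 192
ALLOWED_ANGLES = (10, 20, 30, 60)

__all__ = [
    "WINDOW_LENGTH",
    "ALLOWED_ANGLES",
    "DiagnosisClass",
    "CLASSES",
    "Saccade",
    "Register",
    "SaccadeDataset",
    "DatasetSplit",
    "SaccadeTableFormatError",
    "DatasetValidationError",
    "read_saccade_table",
    "write_saccade_table",
    "split_registers",
]


class SaccadeTableFormatError(ValueError):
    """Raised when an on-disk table does not match the expected schema."""


class DatasetValidationError(ValueError):
    """Raised when dataset invariants (label consistency, referential
    integrity, window length) are violated."""


class DiagnosisClass(enum.Enum):
    """Diagnosis outcome: control, presymptomatic or sick.

    The total order used for tie-breaking everywhere in this package is
    severity: S > P > C.
    """

    C = "C"
    P = "P"
    S = "S"

    @property
    def severity(self) -> int:
        return {"C": 0, "P": 1, "S": 2}[self.value]

    def __lt__(self, other: "DiagnosisClass") -> bool:
        if not isinstance(other, DiagnosisClass):
            return NotImplemented
        return self.severity < other.severity

    @classmethod
    def from_token(cls, token: str) -> "DiagnosisClass":
        try:
            return cls(str(token).strip().upper())
        except ValueError:
            raise DatasetValidationError(
                f"unknown diagnosis label {token!r}; expected one of C, P, S"
            ) from None


#: Canonical class ordering (confusion-matrix axes, metric reports).
CLASSES: tuple[DiagnosisClass, ...] = (
    DiagnosisClass.C,
    DiagnosisClass.P,
    DiagnosisClass.S,
)


@dataclass
class Saccade:
    """One windowed saccade plus its labels.

    ``samples`` holds 192 amplitude values in degrees.  ``working_label``
    starts equal to ``given_label``; only the SOM relabeling stage changes
    it.  ``true_shape_label`` is populated by the synthetic generator only
    and records which shape family the waveform was actually drawn from.
    """

    id: str
    register_id: str
    stimulus_angle: int
    samples: np.ndarray
    given_label: DiagnosisClass
    working_label: DiagnosisClass = None  # type: ignore[assignment]
    true_shape_label: DiagnosisClass | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.shape[0] != WINDOW_LENGTH:
            raise DatasetValidationError(
                f"saccade {self.id!r}: expected {WINDOW_LENGTH} samples, "
                f"got shape {self.samples.shape}"
            )
        if int(self.stimulus_angle) not in ALLOWED_ANGLES:
            raise DatasetValidationError(
                f"saccade {self.id!r}: stimulus angle {self.stimulus_angle} "
                f"not in {ALLOWED_ANGLES}"
            )
        self.stimulus_angle = int(self.stimulus_angle)
        if self.working_label is None:
            self.working_label = self.given_label


@dataclass
class Register:
    """All saccades from one subject, under one diagnosis."""

    id: str
    diagnosis: DiagnosisClass
    saccade_ids: list[str]

    def __post_init__(self) -> None:
        if not self.saccade_ids:
            raise DatasetValidationError(f"register {self.id!r} has no saccades")


@dataclass
class SaccadeDataset:
    """A validated collection of registers and their saccades."""

    registers: list[Register]
    saccades: list[Saccade]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        reg_by_id = {r.id: r for r in self.registers}
        if len(reg_by_id) != len(self.registers):
            raise DatasetValidationError("duplicate register ids")
        sac_by_id = {s.id: s for s in self.saccades}
        if len(sac_by_id) != len(self.saccades):
            raise DatasetValidationError("duplicate saccade ids")
        referenced: set[str] = set()
        for reg in self.registers:
            for sid in reg.saccade_ids:
                if sid not in sac_by_id:
                    raise DatasetValidationError(
                        f"register {reg.id!r} references missing saccade {sid!r}"
                    )
                sac = sac_by_id[sid]
                if sac.register_id != reg.id:
                    raise DatasetValidationError(
                        f"saccade {sid!r} claims register {sac.register_id!r} "
                        f"but is listed under {reg.id!r}"
                    )
                if sac.given_label is not reg.diagnosis:
                    raise DatasetValidationError(
                        f"saccade {sid!r} given_label {sac.given_label.value} "
                        f"!= register diagnosis {reg.diagnosis.value}"
                    )
                referenced.add(sid)
        orphans = set(sac_by_id) - referenced
        if orphans:
            raise DatasetValidationError(
                f"orphan saccades not referenced by any register: {sorted(orphans)[:5]}"
            )

    # -- convenience accessors -------------------------------------------

    @property
    def register_ids(self) -> list[str]:
        return [r.id for r in self.registers]

    def register(self, register_id: str) -> Register:
        for r in self.registers:
            if r.id == register_id:
                return r
        raise KeyError(register_id)

    def saccades_of(self, register_id: str) -> list[Saccade]:
        sac_by_id = {s.id: s for s in self.saccades}
        return [sac_by_id[sid] for sid in self.register(register_id).saccade_ids]

    def registers_by_class(self) -> dict[DiagnosisClass, list[Register]]:
        out: dict[DiagnosisClass, list[Register]] = {c: [] for c in CLASSES}
        for r in self.registers:
            out[r.diagnosis].append(r)
        return out

    def subset(self, register_ids: Sequence[str], provenance: str = "") -> "SaccadeDataset":
        wanted = set(register_ids)
        regs = [r for r in self.registers if r.id in wanted]
        keep = {sid for r in regs for sid in r.saccade_ids}
        sacs = [replace(s, samples=s.samples.copy()) for s in self.saccades if s.id in keep]
        return SaccadeDataset(regs, sacs, provenance or self.provenance)

    def sample_matrix(self) -> np.ndarray:
        return np.stack([s.samples for s in self.saccades])


@dataclass(frozen=True)
class DatasetSplit:
    """Register-level train/validation/test partition."""

    train_register_ids: tuple[str, ...]
    val_register_ids: tuple[str, ...]
    test_register_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        groups = (
            set(self.train_register_ids),
            set(self.val_register_ids),
            set(self.test_register_ids),
        )
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise DatasetValidationError("split partitions overlap")


# ---------------------------------------------------------------------------
# I/O — canonical CSV and matrix-plus-metadata layouts
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = [f"s{i:03d}" for i in range(WINDOW_LENGTH)]
_META_COLUMNS = ["saccade_id", "register_id", "angle", "given_label", "working_label"]


def _dataset_from_frame(meta: pd.DataFrame, samples: np.ndarray, provenance: str) -> SaccadeDataset:
    saccades: list[Saccade] = []
    for i, row in enumerate(meta.itertuples(index=False)):
        given = DiagnosisClass.from_token(row.given_label)
        working = (
            DiagnosisClass.from_token(row.working_label)
            if getattr(row, "working_label", None) is not None
            else given
        )
        true_shape = getattr(row, "true_shape_label", None)
        if true_shape is not None and not (isinstance(true_shape, float) and math.isnan(true_shape)):
            true_shape = DiagnosisClass.from_token(true_shape)
        else:
            true_shape = None
        saccades.append(
            Saccade(
                id=str(row.saccade_id),
                register_id=str(row.register_id),
                stimulus_angle=int(row.angle),
                samples=samples[i],
                given_label=given,
                working_label=working,
                true_shape_label=true_shape,
            )
        )
    members: dict[str, list[str]] = {}
    diagnosis: dict[str, DiagnosisClass] = {}
    order: list[str] = []
    for s in saccades:
        if s.register_id not in members:
            members[s.register_id] = []
            diagnosis[s.register_id] = s.given_label
            order.append(s.register_id)
        members[s.register_id].append(s.id)
    registers = [Register(rid, diagnosis[rid], members[rid]) for rid in order]
    return SaccadeDataset(registers, saccades, provenance)


def read_saccade_table(
    path: str | Path,
    format: str = "csv",
    metadata_path: str | Path | None = None,
) -> SaccadeDataset:
    """Load a saccade dataset.

    ``format="csv"`` reads the canonical single-file layout: columns
    ``saccade_id, register_id, angle, given_label, working_label,
    [true_shape_label,] s000..s191``.  ``format="matrix"`` reads a
    headerless numeric matrix with 192 columns from ``path`` and a
    row-aligned metadata CSV (columns ``register_id, angle, label``) from
    ``metadata_path``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        frame = pd.read_csv(path, comment="#")
        missing = [c for c in _META_COLUMNS if c not in frame.columns]
        if missing:
            raise SaccadeTableFormatError(f"missing columns: {missing}")
        sample_cols = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()]
        if sample_cols != _SAMPLE_COLUMNS:
            raise SaccadeTableFormatError(
                f"expected sample columns s000..s191, found {len(sample_cols)}"
            )
        samples = frame[_SAMPLE_COLUMNS].to_numpy(dtype=np.float64)
        bad = np.nonzero(~np.isfinite(samples).all(axis=1))[0]
        if bad.size:
            raise SaccadeTableFormatError(f"non-numeric sample values in row {bad[0]}")
        meta_cols = _META_COLUMNS + (
            ["true_shape_label"] if "true_shape_label" in frame.columns else []
        )
        return _dataset_from_frame(frame[meta_cols], samples, provenance=str(path))
    if format in ("matrix", "matrix+metadata"):
        if metadata_path is None:
            raise SaccadeTableFormatError("matrix format requires metadata_path")
        samples = pd.read_csv(path, header=None).to_numpy(dtype=np.float64)
        if samples.ndim != 2 or samples.shape[1] != WINDOW_LENGTH:
            raise SaccadeTableFormatError(
                f"matrix must have {WINDOW_LENGTH} columns, got {samples.shape}"
            )
        meta = pd.read_csv(metadata_path)
        if len(meta) != samples.shape[0]:
            raise SaccadeTableFormatError(
                f"metadata rows ({len(meta)}) != matrix rows ({samples.shape[0]})"
            )
        label_col = "label" if "label" in meta.columns else "given_label"
        if label_col not in meta.columns or "register_id" not in meta.columns:
            raise SaccadeTableFormatError("metadata needs register_id and label columns")
        frame = pd.DataFrame(
            {
                "saccade_id": meta.get("saccade_id", pd.Series(range(len(meta)))).astype(str),
                "register_id": meta["register_id"].astype(str),
                "angle": meta.get("angle", pd.Series([30] * len(meta))),
                "given_label": meta[label_col],
                "working_label": meta.get("working_label", meta[label_col]),
            }
        )
        return _dataset_from_frame(frame, samples, provenance=str(path))
    raise ValueError(f"unknown format {format!r}")


def write_saccade_table(dataset: SaccadeDataset, path: str | Path, raw: bool = False) -> None:
    """Write the canonical CSV layout. ``raw=True`` flags a table whose
    samples are pre-normalization (comment header carries the flag)."""
    if not dataset.registers:
        raise DatasetValidationError("refusing to write an empty dataset")
    path = Path(path)
    data: dict[str, list] = {
        "saccade_id": [s.id for s in dataset.saccades],
        "register_id": [s.register_id for s in dataset.saccades],
        "angle": [s.stimulus_angle for s in dataset.saccades],
        "given_label": [s.given_label.value for s in dataset.saccades],
        "working_label": [s.working_label.value for s in dataset.saccades],
    }
    if any(s.true_shape_label is not None for s in dataset.saccades):
        data["true_shape_label"] = [
            s.true_shape_label.value if s.true_shape_label is not None else ""
            for s in dataset.saccades
        ]
    frame = pd.DataFrame(data)
    samples = pd.DataFrame(dataset.sample_matrix(), columns=_SAMPLE_COLUMNS)
    frame = pd.concat([frame, samples], axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# eogsacc saccade table normalized={'false' if raw else 'true'}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Register-stratified splitting
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_registers(
    dataset: SaccadeDataset,
    fractions: Sequence[float] = (0.4, 0.4, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified register split.

    Within each diagnosis class of size n, train receives
    round(f_train * n) registers and validation round(f_val * n) (nearest
    integer, half up); test takes the remainder.  Membership is a seeded
    permutation; counts therefore do not depend on the seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("need three non-negative fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for cls in CLASSES:
        ids = sorted(r.id for r in dataset.registers if r.diagnosis is cls)
        if not ids:
            raise ValueError(f"class {cls.value} has no registers")
        n = len(ids)
        n_train = _round_half_up(fractions[0] * n)
        n_val = _round_half_up(fractions[1] * n)
        n_test = n - n_train - n_val
        if n_test <= 0:
            raise ValueError(
                f"class {cls.value} (n={n}) would receive {n_test} test "
                f"registers under fractions {fractions}; adjust fractions"
            )
        perm = list(rng.permutation(ids))
        train += perm[:n_train]
        val += perm[n_train : n_train + n_val]
        test += perm[n_train + n_val :]
    return DatasetSplit(tuple(train), tuple(val), tuple(test), fractions, int(seed))
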