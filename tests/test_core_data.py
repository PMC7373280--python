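import numpy as np
import pytest

from eogsacc.core_data import (
    DatasetValidationError,
    DiagnosisClass,
    Register,
    Saccade,
    SaccadeDataset,
    SaccadeTableFormatError,
    read_saccade_table,
    split_registers,
    write_saccade_table,
)
from eogsacc.synthetic import GeneratorConfig, generate_dataset

from conftest import C, P, S, make_saccade


class TestDiagnosisClass:
    def test_three_values(self):
        assert [c.value for c in DiagnosisClass] == ["C", "P", "S"]

    def test_severity_order(self):
        assert S > P > C

    def test_from_token_rejects_unknown(self):
        with pytest.raises(DatasetValidationError):
            DiagnosisClass.from_token("X")


class TestSaccade:
    def test_wrong_length_rejected(self):
        with pytest.raises(DatasetValidationError):
            Saccade("x", "r", 30, np.zeros(191), C)

    def test_bad_angle_rejected(self):
        with pytest.raises(DatasetValidationError):
            Saccade("x", "r", 45, np.zeros(192), C)

    def test_working_label_defaults_to_given(self):
        s = make_saccade("x", "r", P)
        assert s.working_label is P


class TestDatasetValidation:
    def test_direct_construction(self, tiny_dataset):
        assert len(tiny_dataset.registers) == 2
        assert len(tiny_dataset.saccades) == 3

    def test_empty_register_rejected(self):
        with pytest.raises(DatasetValidationError):
            Register("r", C, [])

    def test_label_mismatch_rejected(self):
        sacs = [make_saccade("a", "r1", P)]
        with pytest.raises(DatasetValidationError):
            SaccadeDataset([Register("r1", C, ["a"])], sacs)

    def test_orphan_rejected(self):
        sacs = [make_saccade("a", "r1", C), make_saccade("b", "r1", C)]
        with pytest.raises(DatasetValidationError, match="orphan"):
            SaccadeDataset([Register("r1", C, ["a"])], sacs)

    def test_missing_reference_rejected(self):
        sacs = [make_saccade("a", "r1", C)]
        with pytest.raises(DatasetValidationError):
            SaccadeDataset([Register("r1", C, ["a", "ghost"])], sacs)


class TestIO:
    def test_roundtrip(self, tiny_dataset, tmp_path):
        path = tmp_path / "t.csv"
        write_saccade_table(tiny_dataset, path)
        back = read_saccade_table(path)
        assert back.register_ids == tiny_dataset.register_ids
        assert [s.id for s in back.saccades] == [s.id for s in tiny_dataset.saccades]
        for a, b in zip(back.saccades, tiny_dataset.saccades):
            np.testing.assert_allclose(a.samples, b.samples, rtol=1e-9)
            assert a.given_label is b.given_label
            assert a.stimulus_angle == b.stimulus_angle

    def test_roundtrip_preserves_true_shape_and_working(self, tmp_path):
        sacs = [
            make_saccade("a", "r1", P, 1.0, true_shape_label=C),
            make_saccade("b", "r1", P, 2.0),
        ]
        sacs[0].working_label = C
        ds = SaccadeDataset([Register("r1", P, ["a", "b"])], sacs)
        path = tmp_path / "t.csv"
        write_saccade_table(ds, path)
        back = read_saccade_table(path)
        assert back.saccades[0].working_label is C
        assert back.saccades[0].given_label is P
        assert back.saccades[0].true_shape_label is C
        assert back.saccades[1].true_shape_label is None

    def test_wrong_sample_count_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        cols = ["saccade_id", "register_id", "angle", "given_label", "working_label"]
        cols += [f"s{i:03d}" for i in range(191)]
        path.write_text(",".join(cols) + "\n" + "a,r,30,C,C" + ",0" * 191 + "\n")
        with pytest.raises(SaccadeTableFormatError):
            read_saccade_table(path)

    def test_unknown_label_rejected(self, tmp_path, tiny_dataset):
        path = tmp_path / "t.csv"
        write_saccade_table(tiny_dataset, path)
        text = path.read_text().replace(",C,C,", ",Z,Z,", 1)
        path.write_text(text)
        with pytest.raises(DatasetValidationError):
            read_saccade_table(path)

    def test_empty_dataset_not_writable(self, tmp_path):
        ds = SaccadeDataset.__new__(SaccadeDataset)
        ds.registers, ds.saccades, ds.provenance = [], [], ""
        with pytest.raises(DatasetValidationError):
            write_saccade_table(ds, tmp_path / "e.csv")

    def test_matrix_plus_metadata_layout(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(4, 192))
        np.savetxt(tmp_path / "m.csv", mat, delimiter=",")
        (tmp_path / "meta.csv").write_text(
            "register_id,angle,label\nr1,10,C\nr1,20,C\nr2,30,P\nr2,60,P\n"
        )
        ds = read_saccade_table(tmp_path / "m.csv", format="matrix",
                                metadata_path=tmp_path / "meta.csv")
        assert len(ds.saccades) == 4
        assert len(ds.registers) == 2
        np.testing.assert_allclose(ds.sample_matrix(), mat, rtol=1e-6)


def _class_sized_dataset(sizes):
    registers, saccades = [], []
    for cls, n in zip((C, P, S), sizes):
        for i in range(n):
            rid = f"{cls.value}{i}"
            sid = f"{rid}s"
            saccades.append(make_saccade(sid, rid, cls))
            registers.append(Register(rid, cls, [sid]))
    return SaccadeDataset(registers, saccades)


class TestSplit:
    def test_reference_class_sizes(self):
        # 38/18/29 registers at 40-40-20 -> (15,15,8), (7,7,4), (12,12,5)
        ds = _class_sized_dataset((38, 18, 29))
        split = split_registers(ds, (0.4, 0.4, 0.2), seed=123)
        for cls, expect in zip("CPS", [(15, 15, 8), (7, 7, 4), (12, 12, 5)]):
            got = tuple(
                sum(1 for r in ids if r.startswith(cls))
                for ids in (split.train_register_ids, split.val_register_ids,
                            split.test_register_ids)
            )
            assert got == expect

    def test_small_class_rounding(self):
        ds = _class_sized_dataset((5, 5, 5))
        split = split_registers(ds, (0.4, 0.4, 0.2), seed=0)
        assert len(split.train_register_ids) == 6
        assert len(split.val_register_ids) == 6
        assert len(split.test_register_ids) == 3

    def test_determinism_and_seed_dependence(self):
        ds = _class_sized_dataset((10, 10, 10))
        a = split_registers(ds, seed=1)
        b = split_registers(ds, seed=1)
        assert a == b
        counts = lambda s: tuple(map(len, (s.train_register_ids, s.val_register_ids,
                                           s.test_register_ids)))
        c = split_registers(ds, seed=2)
        assert counts(a) == counts(c)

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_invariant_to_seed(self, seed):
        # per-class: C 7 -> (3,3,1), P 5 -> (2,2,1), S 9 -> (4,4,1)
        ds = _class_sized_dataset((7, 5, 9))
        split = split_registers(ds, seed=seed)
        assert len(split.train_register_ids) == 3 + 2 + 4
        assert len(split.val_register_ids) == 3 + 2 + 4
        assert len(split.test_register_ids) == 1 + 1 + 1

    def test_zero_test_class_raises(self):
        ds = _class_sized_dataset((2, 5, 5))
        with pytest.raises(ValueError, match="test"):
            split_registers(ds, (0.5, 0.5, 0.0), seed=0)

    def test_partition_covers_everything(self, default_dataset):
        split = split_registers(default_dataset, seed=9)
        all_ids = (set(split.train_register_ids) | set(split.val_register_ids)
                   | set(split.test_register_ids))
        assert all_ids == set(default_dataset.register_ids)

    def test_bad_fractions(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_registers(tiny_dataset, (0.5, 0.2, 0.2), seed=0)
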