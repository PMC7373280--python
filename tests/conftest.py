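import numpy as np
import pytest

from eogsacc.core_data import DiagnosisClass, Register, Saccade, SaccadeDataset
from eogsacc.synthetic import GeneratorConfig, ShapeParams, generate_dataset

C, P, S = DiagnosisClass.C, DiagnosisClass.P, DiagnosisClass.S


def make_saccade(sid, reg, label, value=0.0, angle=30, **kw):
    return Saccade(
        id=sid,
        register_id=reg,
        stimulus_angle=angle,
        samples=np.full(192, value),
        given_label=label,
        **kw,
    )


@pytest.fixture
def tiny_dataset():
    """Two registers, three constant saccades."""
    saccades = [
        make_saccade("a", "r1", C, 1.0),
        make_saccade("b", "r1", C, 2.0),
        make_saccade("c", "r2", P, 3.0),
    ]
    registers = [Register("r1", C, ["a", "b"]), Register("r2", P, ["c"])]
    return SaccadeDataset(registers, saccades, "fixture")


@pytest.fixture(scope="session")
def default_dataset():
    """Seeded default synthetic dataset (30 registers)."""
    return generate_dataset(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def separable_shapes():
    """Widely separated, noise-free class shapes (pure SOM cells)."""
    return {
        C: ShapeParams(rise_tau=1.0, noise_sd=0.0, baseline_sd=0.0),
        P: ShapeParams(rise_tau=12.0, noise_sd=0.0, baseline_sd=0.0),
        S: ShapeParams(rise_tau=40.0, dysmetria_fraction=0.3, noise_sd=0.0, baseline_sd=0.0),
    }
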