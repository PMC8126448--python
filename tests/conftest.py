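import numpy as np
import pandas as pd
import pytest

from metabodnm.dataio import CONDITIONS, IntensityTensor
from metabodnm.synth import SynthConfig, generate_paired_metabolome


@pytest.fixture
def toy_tensor():
    """2 metabolites x 2 subjects x 2 conditions with hand-checkable values."""
    vals = np.array(
        [
            [[100.0, 200.0], [200.0, 800.0]],  # d = (1, 2), lfc = 1.5
            [[50.0, 100.0], [100.0, 200.0]],  # fasted = 2 x post, lfc = 1
        ]
    ).transpose(0, 2, 1)  # -> (metab, individual, condition)? build explicitly below
    # build explicitly: values[g, i, c]
    vals = np.empty((2, 2, 2))
    vals[0, :, 0] = [100.0, 200.0]  # post
    vals[0, :, 1] = [200.0, 800.0]  # fasted
    vals[1, :, 0] = [50.0, 100.0]
    vals[1, :, 1] = [100.0, 200.0]
    return IntensityTensor(vals, ["M1", "M2"], ["D1", "D2"], CONDITIONS)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic dataset, shared across tests."""
    return generate_paired_metabolome(SynthConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tensor(values, metabolites=None, individuals=None, annotations=None):
    values = np.asarray(values, dtype=float)
    g, i, _ = values.shape
    metabolites = metabolites or [f"M{j+1}" for j in range(g)]
    individuals = individuals or [f"D{j+1}" for j in range(i)]
    return IntensityTensor(values, metabolites, individuals, CONDITIONS, annotations)
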