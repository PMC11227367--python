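import numpy as np
import pandas as pd
import pytest

from diogene.data_model import ExpressionMatrix, PriorMatrix
from diogene.synthetic import SynthParams, generate


@pytest.fixture(scope="session")
def tiny_system():
    """Small linear system: 8 regulators, 6 targets, 30 samples."""
    return generate(
        SynthParams(
            n_regulators=8,
            n_targets=6,
            n_samples=30,
            density=0.15,
            unknown_frac=0.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_system():
    """The benchmark conditions: 20 regulators, 30 targets, 40 samples."""
    return generate(seed=11)


@pytest.fixture()
def toy_expression():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.standard_normal((5, 12)),
        index=[f"g{i}" for i in range(1, 6)],
        columns=[f"s{j}" for j in range(1, 13)],
    )
    return ExpressionMatrix(values=values, regulator_ids=["g1", "g2", "g3"])


@pytest.fixture()
def toy_prior():
    pi = pd.DataFrame(
        [[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["g4", "g5"],
    )
    return PriorMatrix(pi=pi)
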