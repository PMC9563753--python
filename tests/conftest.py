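import numpy as np
import pandas as pd
import pytest

from sulfascreen import workflow
from sulfascreen.synthetic import GeneratorConfig, simulate_study


@pytest.fixture(scope="session")
def plasma_small():
    """A small default-effect plasma study shared across tests."""
    cfg = GeneratorConfig(seed=11, matrix="plasma", n_controls=60, n_cases=60, n_qc=6)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def plasma_small_quant(plasma_small):
    return workflow.quantify(plasma_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(values: dict, loq: float = 8000.0, is_channels=()):
    """Tiny IntensityMatrix helper: values maps column -> list per sample."""
    from sulfascreen.ingest import IntensityMatrix

    df = pd.DataFrame(values)
    df.index = [f"s{i}" for i in range(len(df))]
    return IntensityMatrix(values=df, loq=loq, is_channels=tuple(is_channels))
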