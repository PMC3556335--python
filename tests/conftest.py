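import numpy as np
import pandas as pd
import pytest

from detriage.formats_io import CountTable
from detriage.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study (substitution noise on)."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free synthetic study."""
    return generate_dataset(SimulationConfig(seed=1, substitution_error_rate=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_count_table(rows, stages=("A", "B"), n_reps=3):
    """Features x samples CountTable from a 2-D array."""
    cols = [f"{st}_{r + 1}" for st in stages for r in range(n_reps)]
    df = pd.DataFrame(
        np.asarray(rows, dtype=int),
        columns=cols,
        index=[f"f{i}" for i in range(len(rows))],
    )
    return CountTable(
        counts=df,
        stages={c: c.rsplit("_", 1)[0] for c in cols},
        replicates={c: int(c.rsplit("_", 1)[1]) for c in cols},
    )
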