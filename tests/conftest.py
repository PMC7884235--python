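import numpy as np
import pandas as pd
import pytest

from aggregatomics.feature_table import SVTable
from aggregatomics.simulate import PlantedAssociation, SimConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Hand-written 3 SV x 2 sample table."""
    counts = pd.DataFrame(
        [[10, 0], [5, 5], [0, 15]],
        index=["SV1", "SV2", "SV3"],
        columns=["A", "B"],
    )
    return SVTable(counts)


@pytest.fixture
def random_table(rng):
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(20, 8)),
        index=[f"SV{i}" for i in range(20)],
        columns=[f"S{j}" for j in range(8)],
    )
    counts.iloc[:, 0] += 1  # no zero-total sample
    return SVTable(counts)


PLANTED = (
    PlantedAssociation("SV1", "SV2", 1, 1.0),
    PlantedAssociation("SV3", "SV4", 1, 1.0),
    PlantedAssociation("SV5", "SV6", 1, 1.0),
    PlantedAssociation("SV7", "SV8", -1, 1.0),
    PlantedAssociation("SV9", "SV10", -1, 1.0),
)


def aggregate_benchmark(seed, n_taxa=30):
    """Experiment-3-style aggregate simulation with five planted edges."""
    config = SimConfig(n_taxa=n_taxa, associations=PLANTED, seed=seed)
    design = [("aggregate", 5.3, 37), ("control", 0.0, 6)]
    return generate_experiment(design, config)
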