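import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methaniche.data import AbundanceTable, SampleMetadata
from methaniche.simulate import BlockSpec, SyntheticConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> AbundanceTable:
    """3 genera x 4 samples, raw counts."""
    values = pd.DataFrame(
        [[2.0, 1.0, 0.0, 4.0], [3.0, 1.0, 0.0, 4.0], [5.0, 8.0, 7.0, 2.0]],
        index=["Prevotella", "Fibrobacter", "Methanobrevibacter"],
        columns=["a1", "a2", "a3", "a4"],
    )
    return AbundanceTable(values, "genus", "counts")


@pytest.fixture
def metadata63() -> SampleMetadata:
    rng = np.random.default_rng(42)
    n = 63
    return SampleMetadata(
        pd.DataFrame(
            {
                "animal_id": [f"animal{j:03d}" for j in range(n)],
                "breed": ["AA", "LIM"] * 31 + ["AA"],
                "diet": ["FOR"] * 32 + ["CONC"] * 31,
                "ch4": rng.uniform(10, 25, n),
            }
        )
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Three planted blocks, ~250 features: quick end-to-end scenario."""
    return SyntheticConfig(
        blocks=[
            BlockSpec(25, 15, response_weight=1.2),
            BlockSpec(20, 10, response_weight=0.8),
            BlockSpec(15, 10, response_weight=0.0),
        ],
        n_background_genes=80,
        n_background_genera=80,
        sequencing_depth=200_000,
    )
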