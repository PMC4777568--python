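from pathlib import Path

import pandas as pd
import pytest

import traitvar as tv

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def tiny_table() -> pd.DataFrame:
    """Hand-written 3-species / 10-individual / 2-plot fixture.

    Global species means: A = 2, B = 16/3, C = 10 (body mass);
    leg lengths are constant within species (A 2, B 4, C 8).
    """
    return tv.read_individual_table(DATA / "tiny_communities.csv")


@pytest.fixture(scope="session")
def default_dataset() -> pd.DataFrame:
    """One full synthetic dataset at the default configuration, seed 0."""
    return tv.generate_dataset(tv.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def focal_dataset(default_dataset) -> pd.DataFrame:
    return tv.filter_focal_species(default_dataset, min_n=50)
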