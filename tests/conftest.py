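import numpy as np
import pandas as pd
import pytest

from ncpart import MorphoTable, default_species_params, simulate_dataset
from ncpart.catalog import default_multivariate_traits


@pytest.fixture()
def tiny_csv(tmp_path):
    """Minimal two-specimen table."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "specimen_id,nest_id,CL,CWb\n"
        "S1,N1,700,600\n"
        "S2,N1,710,615\n")
    return path


@pytest.fixture(scope="session")
def synthetic():
    """One medium synthetic dataset shared across tests (seed 7)."""
    params = default_species_params()
    table, labels = simulate_dataset(params, 10, 2, np.random.default_rng(7))
    return table, labels


@pytest.fixture(scope="session")
def analysis_traits(synthetic):
    table, _ = synthetic
    return default_multivariate_traits(available=tuple(table.trait_columns))


def make_table(traits: dict, nest_ids=None, species=None) -> MorphoTable:
    """Build a MorphoTable from a dict of trait-code -> values."""
    frame = pd.DataFrame(traits)
    n = len(frame)
    frame.index = [f"S{i + 1}" for i in range(n)]
    frame.index.name = "specimen_id"
    frame["nest_id"] = nest_ids if nest_ids is not None else [f"N{i + 1}" for i in range(n)]
    if species is not None:
        frame["species"] = species
    return MorphoTable(frame, [c for c in traits])
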