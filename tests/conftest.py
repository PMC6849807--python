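import numpy as np
import pandas as pd
import pytest

from sporetrace.simulate import compute_truth, default_config, generate_dataset
from sporetrace.tables_io import CountTable, SampleRecord, StationClass


@pytest.fixture(scope="session")
def sim_config():
    return default_config()


@pytest.fixture(scope="session")
def sim_truth(sim_config):
    return compute_truth(sim_config)


@pytest.fixture(scope="session")
def dataset(sim_config, tmp_path_factory):
    """One default synthetic run (seed 11), written to disk once per session."""
    out = tmp_path_factory.mktemp("sim") / "run"
    return generate_dataset(sim_config, seed=11, out_dir=out)


@pytest.fixture
def tiny_counts():
    df = pd.DataFrame(
        {"S1": [0, 5, 7], "S2": [3, 0, 9]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    return CountTable(df)


@pytest.fixture
def two_station_meta():
    return [
        SampleRecord("S1", "A", StationClass.NON_TIDAL, 0.0),
        SampleRecord("S2", "A", StationClass.NON_TIDAL, 24.0),
    ]
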