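from pathlib import Path

import pytest

from wpal import synthetic_data as sd

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_truth():
    """One fully simulated ZW pair shared by read-only tests."""
    return sd.simulate_zw_pair(sd.SimulationConfig(seed=1))


@pytest.fixture()
def data_dir():
    return DATA_DIR
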