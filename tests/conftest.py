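import warnings

import numpy as np
import pandas as pd
import pytest

from fnirsgait.core import EventTable, Recording, default_montage
from fnirsgait.synth import GroundTruth, ProtocolSpec, generate_session

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def session_one_run():
    """One default-protocol run with ground truth (shared, read-only)."""
    return generate_session(ProtocolSpec(n_runs=1), GroundTruth(),
                            {"group": "PD"}, seed=101, store_clean=True)


@pytest.fixture()
def simple_recording():
    rng = np.random.default_rng(7)
    rows = pd.DataFrame({
        "channel": ["S1-D1", "S1-D1", "S2-D2", "S2-D2"],
        "wavelength_nm": [760.0, 850.0, 760.0, 850.0],
        "chromophore": ["n/a"] * 4,
    })
    data = 1.0 + 0.1 * rng.standard_normal((4, 600))
    return Recording(data, 50.0, "raw_intensity", rows, run_id="run-01")


def make_events(rows):
    return EventTable(pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                                  "trigger", "source"]))
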