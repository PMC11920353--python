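import numpy as np
import pytest
from hypothesis import settings

import ephysbatch as eb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: the validation step protocol: 115-815 ms, 700 ms injection
WINDOW = eb.ProtocolWindow(115.0, 815.0)


@pytest.fixture(scope="session")
def window():
    return WINDOW


def make_sweep(time, voltage, current=None, index=0):
    """Build a Sweep from arrays, defaulting to zero current."""
    time = np.asarray(time, float)
    if current is None:
        current = np.zeros_like(time)
    return eb.Sweep(index=index, time=time, voltage=np.asarray(voltage, float),
                    current=np.asarray(current, float))


@pytest.fixture(scope="session")
def default_cell_result(window):
    """One noiseless default cell, simulated and fully analysed."""
    rec, truth = eb.simulate_recording(eb.CellParams())
    cfg = eb.AnalysisConfig(window=window)
    return eb.analyze_recording(rec, cfg), truth


@pytest.fixture(scope="session")
def fixture_batch(tmp_path_factory):
    """A 3-cell noiseless delimited fixture batch on disk."""
    folder = tmp_path_factory.mktemp("batch")
    manifest, truths = eb.write_fixture_batch(str(folder), 3, seed=1)
    return folder, manifest, truths
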