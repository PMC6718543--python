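import numpy as np
import pytest

from lfass.model import DFAssayModel
from lfass.plate_io import RawTrace, TimeGrid


@pytest.fixture(scope="session")
def grid8h() -> TimeGrid:
    """2-min cadence over 8 h (acute-stress recording)."""
    return TimeGrid(np.arange(0.0, 480.001, 2.0), 2.0)


@pytest.fixture()
def make_trace(grid8h):
    def _make(f, well="A1", grid=None):
        return RawTrace(well, grid or grid8h, np.asarray(f, dtype=float))
    return _make


@pytest.fixture(scope="session")
def stress384_fit():
    """Fitted default stress plate, shared across tests (deterministic)."""
    model = DFAssayModel.from_simulation("stress384", seed=42)
    results = model.fit()
    merged = results.frame.merge(model.truth, on="well")
    return model, results, merged


def staircase(times: np.ndarray, death_times) -> np.ndarray:
    """Instantaneous-burst, non-decaying population trace: one unit step
    per death."""
    f = np.zeros_like(times, dtype=float)
    for td in death_times:
        f += (times >= td).astype(float)
    return f
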