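import numpy as np
import pytest

from neoripple.synth import SyntheticSpec, make_recording


@pytest.fixture(scope="session")
def default_recording():
    """One medium-length synthetic recording shared across detector tests."""
    spec = SyntheticSpec(duration_s=300.0, spw_rate=4.0, seed=11)
    ts, spikes, truth = make_recording(spec)
    return spec, ts, spikes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def overlaps_any(table, start, stop):
    """True if any event row overlaps the half-open interval [start, stop)."""
    return any(
        (r.start_s < stop) and (start < r.stop_s) for r in table.itertuples()
    )
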