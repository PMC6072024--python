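import numpy as np
import pytest

from neulite import fixtures
from neulite.morphology import discretize, load_swc


@pytest.fixture
def ball_stick(tmp_path):
    """Discretized ball-and-stick morphology: 8 μm soma, 200 μm dendrite."""
    path = fixtures.ball_and_stick_swc(8.0, 200.0, 21,
                                       str(tmp_path / "bs.swc"))
    return discretize(load_swc(path), 20.0)


@pytest.fixture
def two_pop_net():
    return fixtures.two_pop_spec(n_exc=12, n_inh=4, seed=7)


@pytest.fixture
def sim_setup(tmp_path):
    """Complete runnable desk-scale two-population simulation setup."""
    return fixtures.two_pop_sim_files(str(tmp_path), n_exc=8, n_inh=3,
                                      seed=3, tstop=40.0, n_ext=6)


def file_sha256(path):
    import hashlib
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
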