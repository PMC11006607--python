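import numpy as np
import pytest

from locusforge.io_formats import SequenceRecord
from locusforge.synthetic_data import make_default_state_fixture, random_sequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def random_record(rng):
    """One fixed 1-kb random sequence at GC 0.41."""
    return SequenceRecord("rand1kb", random_sequence(rng, 1000, 0.41))


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The end-to-end two-default-states dataset, built once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return make_default_state_fixture(seed=1, out_dir=out), out
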