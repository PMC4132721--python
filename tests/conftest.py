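import numpy as np
import pytest

from trnaip import AnalogSpec, LibrarySpec, RateScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_scheme():
    """Package-default kinetics over a 100-nt track: fast, weakly lossy steps."""
    return RateScheme.uniform(100, k_U=200.0, k_D=1.0, k_act=0.02, baseline_amplitude=0.9)


@pytest.fixture
def small_scheme():
    """Short chain for cheap exact checks."""
    return RateScheme.uniform(5, k_U=2.0, k_D=0.5, k_act=0.05, baseline_amplitude=0.8)


@pytest.fixture
def plain_library():
    return LibrarySpec(
        track_length=100,
        analogs=(AnalogSpec("2'-deoxy-NaS", incorporation_prob=0.05),),
        n_molecules=50_000,
    )
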