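import numpy as np
import pytest

from kincoex import ProtocolSpec, SolverOptions, default_two_member


@pytest.fixture
def two_member():
    """Shipped cooperator/cheater model."""
    return default_two_member()


@pytest.fixture
def fast_solver():
    """Boundary-only output, default extinction floor."""
    return SolverOptions(output_resolution=None)


@pytest.fixture
def continuum_solver():
    """Boundary-only output, no extinction cutoff (continuum regime)."""
    return SolverOptions(output_resolution=None, extinction_floor=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240110)
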