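import numpy as np
import pytest

from poreslab import SimParams
from poreslab.engine import run_ensemble


@pytest.fixture(scope="session")
def params25() -> SimParams:
    """Desk-scale reference point: N=25, kappa=10, E=5, R=5."""
    return SimParams(n_bonds=25, kappa=10.0, e_field=5.0, r_sep=5.0,
                     max_mcs=5_000_000)


@pytest.fixture(scope="session")
def params_small() -> SimParams:
    """A fast point for protocol tests: short, strongly driven chain."""
    return SimParams(n_bonds=10, kappa=5.0, e_field=8.0, r_sep=5.0,
                     max_mcs=2_000_000)


@pytest.fixture(scope="session")
def small_ensemble(params_small):
    """Shared 12-sample ensemble reused across engine/observables tests."""
    return run_ensemble(params_small, n_samples=12, base_seed=77)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
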