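import warnings

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from apcmort.data import load_bundled
from apcmort.model import MCMCConfig, ModelSpec, fit


@pytest.fixture(scope="session")
def bundled():
    return load_bundled()


@pytest.fixture(scope="session")
def ac_fit(bundled):
    """One converged age-cohort fit on the published counts, shared by every
    test that inspects the selected model's posterior."""
    draws = fit(bundled, ModelSpec.from_code("ac"), MCMCConfig(seed=1))
    assert draws.converged, draws.diagnostics
    return draws


@pytest.fixture()
def quiet():
    """Suppress convergence warnings for deliberately tiny sampler budgets."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
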