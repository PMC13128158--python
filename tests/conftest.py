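import pytest

from cdsadopt import default_params, integrate, run_scenario
from cdsadopt.scenarios import canonical_scenarios


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def baseline_trajectory(params):
    return integrate(params)


@pytest.fixture(scope="session")
def canonical_results():
    """The three canonical scenario runs, integrated once per session."""
    return [run_scenario(spec) for spec in canonical_scenarios()]
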