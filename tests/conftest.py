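import logging

import pytest
from hypothesis import HealthCheck, settings

from tavi_cea import load_inputs, run_comparison
from tavi_cea.pipeline import lifetables_for

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the default inputs intentionally carry zero end-of-life/transport costs;
# silence the expected warnings in test output
logging.getLogger("tavi_cea.parameters").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    return load_inputs()


@pytest.fixture(scope="session")
def tables(bundle):
    return lifetables_for(bundle.config)


@pytest.fixture(scope="session")
def base_result(bundle, tables):
    return run_comparison(bundle, tables)
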