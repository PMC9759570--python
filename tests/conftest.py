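import numpy as np
import pytest

from steatopk import default_config, fixture_fig10


@pytest.fixture(scope="session")
def fig10():
    """Packaged worked-example params and the noiseless series they generate."""
    return fixture_fig10()


@pytest.fixture()
def config():
    # function-scoped: several tests mutate the returned config
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
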