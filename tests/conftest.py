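import numpy as np
import pytest

from circinfer import ModelParams, build_trial_set


@pytest.fixture(scope="session")
def trials130():
    return build_trial_set(130, seed=1)


@pytest.fixture(scope="session")
def trials81():
    return build_trial_set(81, seed=0)


@pytest.fixture(scope="session")
def grid_logits(trials81):
    """Logit pairs covering all 81 grid cells."""
    return trials81["L_p"].to_numpy(), trials81["L_s"].to_numpy()


@pytest.fixture
def cini_params():
    return ModelParams(w_p=0.6, w_s=0.4, a_p=0.2, a_s=0.1)


@pytest.fixture(scope="session")
def random_param_draws():
    rng = np.random.default_rng(42)
    return [
        ModelParams(*draw)
        for draw in rng.uniform(0.0, 1.0, size=(100, 4))
    ]
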