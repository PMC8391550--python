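import numpy as np
import pytest

from hsitissue import SceneConfig, WavelengthGrid, make_cohort


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale scene config small enough for per-test training."""
    return SceneConfig(height=48, width=48, seed=7, max_annotated_per_class=80)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return make_cohort(tiny_config, 3)


@pytest.fixture(scope="session")
def separable_cohort(tiny_config):
    """Zero-variability cohort: every class emits exactly its mean curve."""
    return make_cohort(tiny_config.zero_variability(), 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
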