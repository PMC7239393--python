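import numpy as np
import pytest

from stipper.core_io import Sample
from stipper.simcohort import SimConfig, make_truth


@pytest.fixture
def almond_female() -> Sample:
    return Sample(id="alm_f0", phenotype="Almond", sex="female")


@pytest.fixture
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture
def canonical_truth(default_cfg):
    """Hemizygous female carrying the canonical 7/14 expansion."""
    return make_truth(default_cfg, "Almond", "female")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
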