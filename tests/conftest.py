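import numpy as np
import pytest

from tmagraph.pipeline import PipelineConfig, process_core
from tmagraph.synthetic import default_spec, generate_core


@pytest.fixture(scope="session")
def default_core():
    """One clustered synthetic core with ground truth (fixed seed)."""
    return generate_core(default_spec(rng_seed=1))


@pytest.fixture(scope="session")
def processed_core(default_core):
    """The default core run through preprocess + segment + graph stages."""
    image, _ = default_core
    return process_core(image, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
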