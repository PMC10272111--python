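import numpy as np
import pytest

from secseq.preprocess import normalize_log
from secseq.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_fixture():
    """Mid-size default-condition dataset shared across read-only tests."""
    cfg = GeneratorConfig(n_cells=4000, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_norm(default_fixture):
    genes, _, _, _ = default_fixture
    return normalize_log(genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
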