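import numpy as np
import pytest

from fuzzycad import (
    CombinerConfig,
    FACTOR_DOMAINS,
    FACTOR_IDS,
    build_default_knowledge_base,
)


@pytest.fixture(scope="session")
def kb():
    return build_default_knowledge_base()


@pytest.fixture(scope="session")
def minmax():
    return CombinerConfig()


@pytest.fixture(scope="session")
def prodsum():
    return CombinerConfig(t_norm="product", s_norm="prob_sum")


def random_in_domain_vectors(n: int, seed: int) -> np.ndarray:
    """Uniform draws inside every factor's domain; (n, 4)."""
    rng = np.random.default_rng(seed)
    cols = [
        rng.uniform(*FACTOR_DOMAINS[fid], size=n) for fid in FACTOR_IDS
    ]
    return np.column_stack(cols)
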