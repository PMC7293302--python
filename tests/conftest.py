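import numpy as np
import pandas as pd
import pytest

import toxgp as tg


@pytest.fixture(scope="session")
def small_dataset():
    """A modest shared-latent dataset reused across read-only tests."""
    cfg = tg.GeneratorConfig(n_compounds=120, n_genes=200, n_bits=64, seed=7)
    dataset, truth = tg.generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture
def toy_signatures():
    """Four perturbations of two compounds with hand-set dose/duration."""
    genes = {f"g{i}": [0, 1, -1, 0] for i in range(3)}
    return pd.DataFrame(
        {
            "compound_id": ["a", "a", "b", "b"],
            "cell_line": ["MCF7", "PC3", "MCF7", "MCF7"],
            "dose": [1.0, 10.0, 5.0, 5.0],
            "duration": [24.0, 24.0, 6.0, 24.0],
            **genes,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
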