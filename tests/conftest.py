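import numpy as np
import pandas as pd
import pytest

from gliomix.synthetic_data import BlockSpec, SimConfig, generate_study
from gliomix.preprocess import center_scale


@pytest.fixture(scope="session")
def strong_dataset():
    """Well-separated 3-class, 2-block study used by several end-to-end tests."""
    cfg = SimConfig(
        n_per_class=(40, 40, 40),
        block_specs=(
            BlockSpec("mrna", p=150, n_informative=14, kind="gaussian", loading_scale=2.0),
            BlockSpec("methylation", p=150, n_informative=14, kind="beta", loading_scale=2.0),
        ),
        class_separation=7.0,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def standardized_blocks(strong_dataset):
    std, scalings = {}, {}
    for b, X in strong_dataset.blocks.items():
        std[b], scalings[b] = center_scale(X)
    return std, scalings


def random_standardized(rng, n, p):
    """A centered, unit-variance Gaussian matrix as a pandas DataFrame."""
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return pd.DataFrame(X, index=[f"S{i}" for i in range(n)],
                        columns=[f"f{j}" for j in range(p)])
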