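import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from leakyforest import ForestParams, generate_null_dataset


@pytest.fixture
def null_train():
    """A small null training set: n=60, k=8, 3 classes."""
    rng = np.random.default_rng(12345)
    frame, tr, te = generate_null_dataset(60, 8, 1, 3, rng)
    return frame.iloc[tr].reset_index(drop=True), frame.iloc[te].reset_index(drop=True)


@pytest.fixture
def small_params():
    return ForestParams(n_trees=25, seed=7)


def random_two_class(rng, k_max=8, n_max=40):
    """Random two-class dataset over at most k_max levels."""
    k = int(rng.integers(2, k_max + 1))
    n = int(rng.integers(k + 2, n_max))
    levels = [chr(ord("a") + i) for i in range(k)]
    x = rng.choice(levels, size=n)
    y = rng.choice(["c1", "c2"], size=n)
    y[:2] = ["c1", "c2"]  # guarantee both classes occur
    return x, y
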