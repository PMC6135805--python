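import numpy as np
import pandas as pd
import pytest

from secrenet.network import PPINetwork


@pytest.fixture
def triangle() -> PPINetwork:
    net = PPINetwork()
    net.add_edge("A", "B", 0.9)
    net.add_edge("B", "C", 0.8)
    net.add_edge("A", "C", 0.7)
    return net


@pytest.fixture
def path_abc() -> PPINetwork:
    net = PPINetwork()
    net.add_edge("A", "B", 0.9)
    net.add_edge("B", "C", 0.9)
    return net


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def make_ranking():
    def _make(rng: np.random.Generator, n: int) -> pd.Series:
        genes = [f"g{i:04d}" for i in range(n)]
        return pd.Series(rng.normal(size=n), index=genes)

    return _make
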