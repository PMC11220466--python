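import io as _stdio

import numpy as np
import pytest

from pathrank import synthetic
from pathrank.models import DrawnPath, Embedding2D, FeatureMatrix


@pytest.fixture(scope="session")
def planted():
    """Default planted-trajectory fixture: 500 x 1000, 10 sinusoidal signals."""
    emb, fm, path, names = synthetic.make_planted_trajectory(seed=7)
    return emb, fm, path, names


@pytest.fixture(scope="session")
def small_planted():
    """A cheap fixture for plumbing tests (shapes, io, cli)."""
    emb, fm, path, names = synthetic.make_planted_trajectory(
        n_samples=120, n_features=40, n_signal=4, seed=3
    )
    return emb, fm, path, names


@pytest.fixture
def tiny_embedding():
    return Embedding2D(["a", "b", "c"], [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


@pytest.fixture
def tiny_features():
    return FeatureMatrix(
        ["a", "b", "c"],
        ["f1", "f2"],
        [[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]],
    )


@pytest.fixture
def unit_path():
    return DrawnPath([[0.0, 0.0], [1.0, 1.0]])


def text_stream(content: str, name: str = "table.csv") -> _stdio.StringIO:
    s = _stdio.StringIO(content)
    s.name = name
    return s


@pytest.fixture
def make_stream():
    return text_stream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
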