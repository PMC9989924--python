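import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from coordscan.synthetic import fixture_F1


@pytest.fixture(scope="session")
def f1():
    """The canonical deterministic fixture: (ExpressionMatrix, GroundTruth)."""
    return fixture_F1()


@pytest.fixture(scope="session")
def f1_matrix(f1):
    return f1[0]


@pytest.fixture(scope="session")
def f1_truth(f1):
    return f1[1]


@pytest.fixture(scope="session")
def f1_oracle_corr(f1_matrix):
    """Independent full correlation matrix: explicit centered-product formula."""
    x = f1_matrix.values
    d = x - x.sum(axis=1, keepdims=True) / x.shape[1]
    ss = (d * d).sum(axis=1)
    return (d @ d.T) / np.sqrt(np.outer(ss, ss))
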