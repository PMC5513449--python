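import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles.py importable


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """6 genes x 4 libraries (2 conditions x 2 times, 1 replicate each)."""
    rng = np.random.default_rng(5)
    values = rng.poisson(30, size=(6, 4))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(1, 7)],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def toy_sheet() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "time": ["d21", "d40", "d21", "d40"],
            "replicate": ["r1", "r1", "r1", "r1"],
            "condition": ["piau", "piau", "commercial", "commercial"],
        }
    )


@pytest.fixture
def two_source_mixture():
    """500 observations of two independent non-Gaussian sources mixed by a
    known 2x2 matrix — the standard ICA recovery benchmark."""
    rng = np.random.default_rng(0)
    m = 500
    s1 = rng.uniform(-np.sqrt(3), np.sqrt(3), m)
    s2 = rng.laplace(0, 1 / np.sqrt(2), m)
    S = np.column_stack([s1, s2])
    A = np.array([[1.0, 0.5], [0.5, 1.0]])
    return S, S @ A.T


@pytest.fixture
def separated_series() -> tuple[pd.DataFrame, np.ndarray]:
    """Two groups of 50 genes with far-separated 4-point count profiles and
    Poisson sampling noise — trivially clusterable ground truth."""
    rng = np.random.default_rng(3)
    a = rng.poisson([100.0, 200.0, 300.0, 400.0], size=(50, 4))
    b = rng.poisson([400.0, 300.0, 200.0, 100.0], size=(50, 4))
    frame = pd.DataFrame(
        np.vstack([a, b]).astype(float),
        index=[f"g{i}" for i in range(100)],
        columns=["t1", "t2", "t3", "t4"],
    )
    truth = np.repeat([1, 2], 50)
    return frame, truth
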