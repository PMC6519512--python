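import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from connstab import EdgeTable


def make_table(
    n0: int = 12,
    n1: int = 12,
    n_roi: int = 8,
    signal: dict[int, float] | None = None,
    seed: int = 0,
    sd: float = 1.0,
) -> EdgeTable:
    """Small Gaussian edge table; ``signal`` maps edge index -> group shift."""
    rng = np.random.default_rng(seed)
    n_edges = n_roi * (n_roi - 1) // 2
    values = rng.normal(0.0, sd, (n0 + n1, n_edges))
    labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    for k, shift in (signal or {}).items():
        values[labels == 1, k] += shift
    return EdgeTable(values, labels=labels, n_roi=n_roi)


@pytest.fixture
def tiny_table() -> EdgeTable:
    return make_table(seed=11)


@pytest.fixture
def signal_table() -> EdgeTable:
    """12 vs 12 subjects, 28 edges, strong shifts on edges 0 and 5."""
    return make_table(signal={0: 2.5, 5: 2.5}, seed=7)
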