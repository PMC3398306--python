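import sys
from pathlib import Path

import numpy as np
import pytest

from targetfish import AssociationTable

sys.path.insert(0, str(Path(__file__).parent))  # make oracle_prw importable


def make_toy_table(rng: np.random.Generator, d=8, n_classes=3, members=4) -> AssociationTable:
    """Small random table with distinct class sizes (members, members+1, ...)."""
    instances, fps = [], {}
    counter = 0
    for j in range(n_classes):
        for _ in range(members + j):
            cid = f"c{counter:03d}"
            counter += 1
            fps[cid] = rng.integers(0, 2, size=d).astype(np.uint8)
            instances.append((cid, f"t{j}"))
    return AssociationTable(instances=tuple(instances), fingerprints=fps)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table(rng):
    return make_toy_table(rng)
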