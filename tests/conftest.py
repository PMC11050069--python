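import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ploidy_consensus.containers import ExpressionDataset, SignatureCollection

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples intensity cohort, 2 diploid + 2 polyploid."""
    matrix = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [1.2, 5.1, 2.1],
            "s3": [3.0, 5.0, 2.0],
            "s4": [3.2, 4.9, 2.2],
        },
        index=["GA", "GB", "GC"],
    )
    return ExpressionDataset(
        name="tiny",
        matrix=matrix,
        sample_groups={"s1": "diploid", "s2": "diploid",
                       "s3": "polyploid", "s4": "polyploid"},
        platform="intensity",
    )


@pytest.fixture
def toy_collection():
    return SignatureCollection(
        sets={
            "S1": frozenset({"A", "B", "C"}),
            "S2": frozenset({"C", "D"}),
        },
        descriptions={"S1": "first", "S2": "second"},
    )


def bh_oracle(p):
    """Brute-force BH step-up: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj
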