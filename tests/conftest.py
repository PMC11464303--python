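import numpy as np
import pandas as pd
import pytest

from climacop import CriteriaSpec, LikertDataset


@pytest.fixture
def two_criteria_spec() -> CriteriaSpec:
    return CriteriaSpec(
        ("C1", "C2"),
        {"C1": "communication", "C2": "awareness"},
        {"communication": "benefit", "awareness": "cost"},
    )


def make_dataset(rows, attrs=None, criteria=("C1", "C2"), ids=None) -> LikertDataset:
    """Small hand-built dataset; ``rows`` is a list of response tuples."""
    n = len(rows)
    attrs = attrs if attrs is not None else {"site": ["A"] * n}
    return LikertDataset(
        ids=ids or [f"r{i}" for i in range(n)],
        attributes=pd.DataFrame(attrs),
        responses=pd.DataFrame(np.asarray(rows, dtype=float), columns=list(criteria)),
    )


@pytest.fixture
def tiny_dataset() -> LikertDataset:
    return make_dataset([(4, 5), (3, 4), (5, 5)])
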