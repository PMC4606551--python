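import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dar import DiscreteDataset, ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset() -> DiscreteDataset:
    """4 samples; geneX labels [+1, +1, -1, 0]; groups [case, case, ctrl, ctrl]."""
    labels = pd.DataFrame(
        [[1, 1, -1, 0]], index=["geneX"], columns=["s1", "s2", "s3", "s4"]
    )
    groups = pd.Series(["case", "case", "ctrl", "ctrl"],
                       index=["s1", "s2", "s3", "s4"])
    return DiscreteDataset(labels=labels, group_of=groups)


@pytest.fixture
def split_dataset() -> DiscreteDataset:
    """One gene +1 in all 8 cases and 0 in all 8 controls, plus a null gene."""
    samples = [f"c{i}" for i in range(8)] + [f"k{i}" for i in range(8)]
    labels = pd.DataFrame(
        [[0] * 8 + [1] * 8, [0, 1] * 8],
        index=["marker", "noise"],
        columns=samples,
    )
    groups = pd.Series(["ctrl"] * 8 + ["case"] * 8, index=samples)
    return DiscreteDataset(labels=labels, group_of=groups)


def make_matrix(values: np.ndarray, groups: list[str]) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        group_of=pd.Series(groups, index=samples),
    )
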