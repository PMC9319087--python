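import numpy as np
import pandas as pd
import pytest

from modbridge import ExpressionMatrix, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_table():
    """6 controls + 6 cases with sex/age covariates."""
    ids = [f"s{i}" for i in range(12)]
    return SampleTable(pd.DataFrame(
        {
            "phenotype": [0] * 6 + [1] * 6,
            "sex": [0, 1] * 6,
            "age": np.linspace(60, 82, 12),
        },
        index=pd.Index(ids, name="sample_id"),
    ))


@pytest.fixture
def small_expression(rng, two_group_table):
    genes = [f"g{i:02d}" for i in range(30)]
    values = rng.normal(size=(30, 12))
    return ExpressionMatrix(genes, two_group_table.sample_ids, values,
                            population="testpop", tissue="cortex")
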