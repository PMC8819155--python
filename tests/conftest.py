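import numpy as np
import pandas as pd
import pytest

from normproxy.datamodel import Domain, SurveySchema, SurveyTable


@pytest.fixture
def tiny_survey() -> SurveyTable:
    df = pd.DataFrame({
        "person_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
        "cluster_id": ["A", "A", "A", "B", "B", "B"],
        "weight": [2.0, 1.0, 1.0, 1.0, 1.0, 2.0],
        "y": [1, 0, 0, 1, 1, 0],
    })
    schema = SurveySchema(weight="weight", items={"y": Domain("binary")})
    return SurveyTable(df, schema)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
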