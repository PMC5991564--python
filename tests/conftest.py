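import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def het_csv(tmp_path):
    """Small valid heteroplasmy CSV on the percentage scale."""
    df = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2"],
            "sex": ["female", "female", "male"],
            "tissue": ["blood", "urine", "muscle"],
            "age_at_sample": [30.0, 30.0, 45.0],
            "level": [25.0, 40.0, 60.0],
        }
    )
    path = tmp_path / "het.csv"
    df.to_csv(path, index=False)
    return path
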