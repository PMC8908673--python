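import numpy as np
import pandas as pd
import pytest

from pdoniche import default_scenario, generate_expression


@pytest.fixture(scope="session")
def cfg():
    return default_scenario(seed=11)


@pytest.fixture(scope="session")
def expr_and_sigs(cfg):
    return generate_expression(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_growth_records(rows):
    """rows: (sample_id, condition, day, replicate, luminescence, is_blank)"""
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "day", "replicate",
                 "luminescence", "is_blank"],
    )
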