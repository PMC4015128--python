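import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcamsea import MetaboliteTable, SyntheticSpec, generate_two_group_matrix

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240221)


@pytest.fixture
def small_table():
    """4x3 complete table with simple integer abundances."""
    values = np.array(
        [
            [1.0, 4.0, 2.0],
            [2.0, 3.0, 5.0],
            [3.0, 2.0, 3.0],
            [4.0, 1.0, 8.0],
        ]
    )
    return MetaboliteTable(values, ["s1", "s2", "s3", "s4"], ["m1", "m2", "m3"])


@pytest.fixture
def synth():
    """Default small synthetic study with known truth."""
    spec = SyntheticSpec(
        n_metabolites=100, n_affected=20, n_pathways=10, seed=11
    )
    table, truth = generate_two_group_matrix(spec)
    return spec, table, truth
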