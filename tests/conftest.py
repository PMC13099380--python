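import numpy as np
import pandas as pd
import pytest

from scovnet import CohortTable, make_atlas
from scovnet.synthetic import fixture_atlas, make_fixture_small


@pytest.fixture(scope="session")
def small_atlas():
    return fixture_atlas()


@pytest.fixture(scope="session")
def fixture_table():
    return make_fixture_small()


@pytest.fixture
def tiny_atlas():
    return make_atlas(
        [
            {"name": "regA", "class": "cortical", "hemisphere": "left"},
            {"name": "regB", "class": "subcortical", "hemisphere": "right"},
        ]
    )


def build_table(atlas, volumes, groups, rng=None):
    """Assemble a CohortTable from a (subjects x regions) volume array."""
    rng = rng or np.random.default_rng(0)
    volumes = np.asarray(volumes, dtype=float)
    n = volumes.shape[0]
    data = pd.DataFrame(volumes, columns=atlas.names)
    data.insert(0, "total_brain_volume", rng.normal(1e6, 1e5, n))
    data.insert(0, "education", rng.integers(0, 5, n).astype(float))
    data.insert(0, "sex", rng.integers(0, 2, n).astype(float))
    data.insert(0, "age", rng.uniform(18, 55, n))
    data.insert(0, "group", groups)
    data.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    return CohortTable(data=data, atlas=atlas)
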