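import numpy as np
import pandas as pd
import pytest

from pollindex import ReferenceTable, study_replica
from pollindex.reference import ELEMENTS


@pytest.fixture(scope="session")
def ucc() -> ReferenceTable:
    return ReferenceTable.ucc_default()


@pytest.fixture(scope="session")
def replica() -> pd.DataFrame:
    """Site-level synthetic study replica (121 sites), seed 1."""
    return study_replica(1)


@pytest.fixture()
def random_matrix() -> pd.DataFrame:
    """Small random concentration matrix with metadata, fixed seed."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=1.0, size=(10, len(ELEMENTS))),
        columns=list(ELEMENTS),
    )
    df.insert(0, "site_id", [f"s{i}" for i in range(10)])
    df["side"] = ["left"] * 5 + ["right"] * 5
    df["distance_m"] = [-0.5, -2.5, -5, -10, -20, 0.5, 2.5, 10, 20, 50]
    return df
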