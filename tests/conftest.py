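import numpy as np
import pandas as pd
import pytest

from tridomain.cohort import CohortConfig, generate_cohort
from tridomain.tables import CountTable, Domain, TaxonomyTable


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-size cohort shared across tests."""
    cfg = CohortConfig(n_samples=48, n_bacteria=20, n_fungi=15, n_nutrients=60,
                       n_blocks=6, seed=42)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    df = pd.DataFrame(
        [[3, 0, 5], [1, 4, 0], [0, 0, 2]],
        index=["GenusA", "GenusB", "GenusC"],
        columns=["s1", "s2", "s3"],
    )
    return CountTable(domain=Domain.BACTERIA, df=df)


@pytest.fixture
def toy_taxonomy():
    rows = {
        "GenusA": ["P1", "C1", "O1", "F1", "GenusA"],
        "GenusB": ["P1", "C1", "O1", "F1", "GenusB"],   # same family as A
        "GenusC": ["P1", "C1", "O2", "F2", "GenusC"],   # shares phylum+class
        "GenusD": ["P2", "C9", "O9", "F9", "GenusD"],   # different phylum
    }
    return TaxonomyTable(df=pd.DataFrame.from_dict(rows, orient="index"))
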