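import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sarcycle import (
    CountMatrix, TaxonomyMap, generate_dataset, presets, rarefy,
    relative_abundance,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> CountMatrix:
    counts = pd.DataFrame(
        [[6, 2, 2], [2, 2, 6], [5, 0, 5]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
    dates = pd.Series(pd.to_datetime(["2016-01-04", "2016-01-14", "2016-01-24"]),
                      index=counts.index)
    return CountMatrix(counts, dates)


@pytest.fixture
def small_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({"a1": "Ia.3", "a2": "Ia.3", "a3": "other"})


@pytest.fixture(scope="session")
def wec_dataset():
    """One weekly multiannual dataset shared by the slower analyses."""
    cfg = presets()["wec_like"]
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def wec_rel_abundance(wec_dataset):
    _, cm, _, _ = wec_dataset
    return relative_abundance(rarefy(cm, seed=1))
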