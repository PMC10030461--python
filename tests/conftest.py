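import numpy as np
import pandas as pd
import pytest

from perimb.core import FeatureTable, SampleMetadata
from perimb.synth import CohortConfig, generate_cohort, _random_tree


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture
def random_table():
    """Factory: seeded random FeatureTable with strictly positive totals."""

    def make(n_samples=10, n_features=20, seed=0, max_count=50):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, max_count, size=(n_samples, n_features))
        counts[:, 0] += 1  # guarantee nonzero totals
        return FeatureTable(
            [f"S{i}" for i in range(n_samples)],
            [f"F{j}" for j in range(n_features)],
            counts,
        )

    return make


@pytest.fixture
def random_tree():
    """Factory: seeded random tree over the given leaf names."""

    def make(leaf_names, seed=0):
        return _random_tree(list(leaf_names), np.random.default_rng(seed))

    return make


@pytest.fixture
def simple_metadata():
    """Factory: minimal metadata over the given sample ids."""

    def make(sample_ids, **columns):
        df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
        df["site"] = columns.pop("site", "VD")
        for k, v in columns.items():
            df[k] = v
        return SampleMetadata(df, validate_twins=False)

    return make
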