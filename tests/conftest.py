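import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from metabotyper import default_spec, simulate


@pytest.fixture(scope="session")
def cohort():
    """One default 2-metabotype cohort shared across tests."""
    return simulate(default_spec(), seed=11)


@pytest.fixture(scope="session")
def autoscaled_cohort(cohort):
    from metabotyper.pretreatment import PretreatmentSpec, pretreat

    x, _ = pretreat(
        cohort.table.values.to_numpy(float), PretreatmentSpec(scaling="center+UV")
    )
    return x


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def table_copy(cohort):
    """Per-test deep copy of the cohort table, safe to mutate."""
    from metabotyper.data_model import MetaboliteTable

    t = cohort.table
    return MetaboliteTable(
        t.values.copy(), t.sample_meta.copy(), t.var_meta.copy(), aggregated=t.aggregated
    )


def two_blobs(n_per=20, sep=5.0, sd=0.1, p=3, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [rng.normal(-sep / 2, sd, (n_per, p)), rng.normal(sep / 2, sd, (n_per, p))]
    )
    labels = np.repeat([1, 2], n_per)
    return x, labels


def three_blobs(n_per=13, sd=0.15, p=4, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(c, sd, (n_per, p)) for c in (0.0, 5.0, 10.0)])
    labels = np.repeat([1, 2, 3], n_per)
    return x, labels
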