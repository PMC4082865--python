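import numpy as np
import pandas as pd
import pytest

from ncanet import (
    bundled_interaction_table,
    generate_regulatory_dataset,
    make_identifiable_topology,
    read_interaction_table,
)


@pytest.fixture(scope="session")
def table_path():
    return bundled_interaction_table()


@pytest.fixture(scope="session")
def interactions(table_path):
    return read_interaction_table(table_path)


@pytest.fixture(scope="session")
def small_topology():
    """Identifiable 3-TF topology restricted to regulated genes."""
    return make_identifiable_topology(20, 3, 6, seed=1).regulated()


@pytest.fixture(scope="session")
def noiseless_dataset(small_topology):
    return generate_regulatory_dataset(small_topology, 10, noise_sd=0.0, seed=2)


@pytest.fixture()
def toy_expr():
    """6-sample, 4-gene two-class toy matrix with hand-checkable statistics."""
    rng = np.random.default_rng(11)
    values = rng.normal(0, 1, size=(4, 6))
    values[0, 3:] += 3.0  # one clearly shifted gene
    expr = pd.DataFrame(
        values,
        index=["GA", "GB", "GC", "GD"],
        columns=[f"S{k}" for k in range(6)],
    )
    labels = ["c", "c", "c", "t", "t", "t"]
    return expr, labels
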