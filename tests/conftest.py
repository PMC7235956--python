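import numpy as np
import pandas as pd
import pytest

from neurocpm.synthetic import (
    SignalSpec,
    SyntheticCohortSpec,
    generate_cohort,
    generate_edge_data,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def item_key():
    """Synthetic 60-item key: 12 items per factor, items 7-12 of each reversed.

    The real instrument's key is copyrighted; this stand-in only has to be
    structurally valid.
    """
    factors = ["neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness"]
    rows = []
    item = 1
    for factor in factors:
        for j in range(12):
            rows.append({"item_id": item, "factor": factor, "reverse": j >= 6})
            item += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects in 20 families of 3, with planted signal on K=20 nodes."""
    spec = SyntheticCohortSpec(
        n_subjects=60, n_families=20, family_size_distribution={3: 1.0}, seed=7
    )
    cohort = generate_cohort(spec)
    signal = SignalSpec(n_nodes=20, n_positive_edges=8, n_negative_edges=8,
                        beta=0.25, noise_sd=0.3, seed=7)
    edges, truth = generate_edge_data(cohort, signal)
    return cohort, edges, truth
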