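import numpy as np
import pytest

from hypermhc import (
    Dataset,
    MHCAllele,
    SimConfig,
    SyntheticBackend,
    generate_dataset,
)

FAST_MODEL = dict(
    n_ensemble=1,
    max_epochs=5,
    early_stop_patience=5,
    head_hidden=(16, 8),
    d_model=16,
    lstm_hidden=8,
)


@pytest.fixture(scope="session")
def backend():
    return SyntheticBackend(seed=7)


@pytest.fixture(scope="session")
def allele():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=34))
    return MHCAllele("DRB1_TEST", seq)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    dataset, _ = generate_dataset(SimConfig(n_records=120, n_alleles=3, seed=5))
    return dataset


@pytest.fixture(scope="session")
def fitted_model(small_dataset, backend):
    """A quickly fitted predictor shared by interpretation tests."""
    from hypermhc.model import dataset_to_xy, HypergraphBindingPredictor

    X, y = dataset_to_xy(small_dataset)
    model = HypergraphBindingPredictor(backend=backend, random_state=3, **FAST_MODEL)
    return model.fit(X, y)
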