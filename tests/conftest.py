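import numpy as np
import pytest

from riskuq import (
    ModelConfig,
    generate_cohort,
    inner_split,
    ntcp_cohort_spec,
    split_cohort,
    train_model,
)


@pytest.fixture(scope="session")
def fast_config():
    return ModelConfig(max_epochs=150, early_stopping_patience=15)


@pytest.fixture(scope="session")
def ntcp_splits():
    """A mid-sized NTCP-style cohort with its development/validation splits."""
    cohort = generate_cohort(ntcp_cohort_spec(n_patients=1600, seed=11))
    dev, ival = split_cohort(cohort, 0.8, seed=11)
    train, valid = inner_split(dev, 0.8, seed=12)
    return {"cohort": cohort, "dev": dev, "ival": ival, "train": train, "valid": valid}


@pytest.fixture(scope="session")
def dysphagia_model(ntcp_splits, fast_config):
    return train_model(
        ntcp_splits["train"], ntcp_splits["valid"], "dysphagia", fast_config, seed=13
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
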