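import dataclasses

import numpy as np
import pytest

from plasmapanel import default_cohort_config, generate_cohort, generate_tau_panel


@pytest.fixture(scope="session")
def default_config():
    return default_cohort_config(seed=0)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default 262-subject cohort with the 76-subject tau panel."""
    coh = generate_cohort(default_config, seed=0)
    return generate_tau_panel(coh, default_config.tau_model, seed=1)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """Large cohort (1,000 per group, no missing centiloid) for law-of-
    large-numbers checks."""
    cfg = dataclasses.replace(
        default_config,
        group_sizes={g: 1000 for g in default_config.group_sizes},
        n_missing_centiloid=0,
    )
    return generate_cohort(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
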