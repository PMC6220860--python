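import numpy as np
import pandas as pd
import pytest

from dgconnect import SyntheticConfig, generate_uptake


@pytest.fixture(scope="session")
def null_study():
    """One deterministic synthetic study with identical groups (no injected edges)."""
    return generate_uptake(SyntheticConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_table():
    """A tiny 2-group, 6-region uptake table for fast connectivity runs."""
    cfg = SyntheticConfig(n_per_group=6, n_regions=6, n_latent=2, seed_regions=(0,), rng_seed=3)
    return generate_uptake(cfg).uptake


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_sections():
    """Hand-set 3-section, 2-region section table for enumeration oracles.

    Region X measured in sections 1-3, region Y only in sections 2-3.
    """
    rows = []
    values = {("X", 1): 10.0, ("X", 2): 12.0, ("X", 3): 14.0, ("Y", 2): 20.0, ("Y", 3): 22.0}
    for (region, sec), v in values.items():
        rows.append(
            {"animal_id": "a1", "group": "control", "region": region,
             "section_index": sec, "value": v, "value_kind": "activity"}
        )
    return pd.DataFrame(rows)
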