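import numpy as np
import pandas as pd
import pytest

from seedcontrast.synthetic_data import OmicsScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    return OmicsScenario(
        n_features_common=20,
        n_specific_a=5,
        n_specific_b=3,
        tissue_effect_sd=2.0,
        noise_sd=0.3,
        ion_multiplicity=2.5,
        dropout_rate=0.15,
        shared_ion_rate=0.1,
        rng_seed=42,
    )


@pytest.fixture
def clean_scenario():
    """Large planted effects, no dropout, no shared ions: exact recovery."""
    return OmicsScenario(
        n_features_common=30,
        n_specific_a=8,
        n_specific_b=4,
        tissue_effect_sd=6.0,
        noise_sd=0.05,
        ion_multiplicity=2.0,
        dropout_rate=0.0,
        shared_ion_rate=0.0,
        rng_seed=7,
    )


def make_ion_row(ion_id, proteins, tissue, replicate, area):
    return {
        "ion_id": ion_id,
        "protein_ids": ";".join(proteins) if isinstance(proteins, (list, tuple))
        else proteins,
        "tissue": tissue,
        "replicate": replicate,
        "area": area,
    }


@pytest.fixture
def ion_table_builder():
    def build(rows):
        return pd.DataFrame(
            rows,
            columns=["ion_id", "protein_ids", "tissue", "replicate", "area"],
        )

    return build
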