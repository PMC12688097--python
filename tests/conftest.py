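from __future__ import annotations

import numpy as np
import pytest

from ohnomir.synthetic import (
    SyntheticConfig,
    generate_annotations,
    generate_expression,
    generate_regulatory_network,
    generate_sequences,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A quick small-genome configuration shared by module tests."""
    return SyntheticConfig(
        n_mirna_genes=80,
        n_target_genes=400,
        n_wgd_pairs=15,
        n_ssd_pairs=15,
        frac_intragenic=0.4,
        n_background_target_pairs=30,
        n_background_ppi_edges=80,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_annotations(small_config)


@pytest.fixture(scope="session")
def small_matures(small_config, small_bundle):
    return generate_sequences(small_config, small_bundle)


@pytest.fixture(scope="session")
def small_netbundle(small_config, small_bundle, small_matures):
    return generate_regulatory_network(small_config, small_bundle, small_matures)


@pytest.fixture(scope="session")
def small_expression(small_config, small_bundle, small_matures):
    return generate_expression(small_config, small_bundle, small_matures)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
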