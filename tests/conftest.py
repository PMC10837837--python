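import numpy as np
import pytest

from ecosig.synthetic_data import (
    CladeParams,
    GenomeSimConfig,
    ProteomeSimConfig,
    make_clade_genomes,
)

# Desk-scale genome configuration for unit tests: same planted clade
# parameters as the defaults, fewer/smaller genomes for speed.
SMALL_CLADES = {
    "Ia": CladeParams(4, 0.470, 8.9, 0.5, 0.26, 5.0, 20.0, 0.18, 0.00, 0.05, 0.62),
    "Ib": CladeParams(4, 0.473, -1.6, 0.5, 0.47, 9.0, 30.0, 0.21, -0.05, 0.05, 0.64),
    "IIa": CladeParams(4, 0.521, 12.1, 6.0, 0.97, 9.0, 20.0, 0.21, -0.05, 0.04, 0.55),
    "IIb": CladeParams(3, 0.481, 45.5, 8.0, 0.80, 7.0, 20.0, 0.20, -0.05, 0.05, 0.58),
}


@pytest.fixture(scope="session")
def small_genome_config():
    return GenomeSimConfig(
        clades=SMALL_CLADES,
        genome_length=40_000,
        n_contigs=2,
        n_cds=20,
        cds_length=600,
        n_promoters=10,
    )


@pytest.fixture(scope="session")
def small_genome_set(small_genome_config):
    return make_clade_genomes(small_genome_config, seed=11)


@pytest.fixture(scope="session")
def small_proteome_config():
    return ProteomeSimConfig(
        clades={"Ia": 4, "Ib": 4, "IIa": 4, "IIb": 3},
        n_families=8,
        protein_length=200,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
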