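import numpy as np
import pytest

from viromeshare import synthetic_data as syn


@pytest.fixture(scope="session")
def small_pool():
    """Deterministic 60-template single-regime pool with genomes."""
    return syn.generate_virus_pool(
        60,
        {"Siphoviridae": 0.5, "Microviridae": 0.3, "Myoviridae": 0.2},
        temperate_fraction=0.6,
        gc_target=0.41,
        seed=42,
    )


@pytest.fixture(scope="session")
def two_group_design():
    return syn.StudyDesign(
        groups=("G1", "G2"),
        weeks=(1, 2),
        diet_by_week={1: "normal", 2: "normal"},
        sharing_within=0.6,
        sharing_between=0.2,
        n_viruses_per_sample=40,
        reads_per_sample=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(two_group_design):
    """2 groups x 2 weeks, 40 contigs per sample, with sequences."""
    viromes, truth, pool = syn.generate_study(two_group_design)
    return viromes, truth, pool


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
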