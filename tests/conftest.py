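import numpy as np
import pytest

from segdup.simulate import SimulationConfig, simulate_scenario

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), n))


def mutate_seq(rng: np.random.Generator, s: str, rate: float) -> str:
    out = list(s)
    for i, c in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != c])
    return "".join(out)


def revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


@pytest.fixture(scope="session")
def small_scenario():
    """A compact single-species scenario with planted duplications."""
    cfg = SimulationConfig(
        newick="(Pxyl);",
        genome_length=200_000,
        n_ancestral=0,
        n_clade_shared=0,
        n_lineage_unique=20,
        seed=11,
    )
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def five_species_scenario():
    """A compact five-species scenario exercising every event category."""
    cfg = SimulationConfig(
        genome_length=150_000,
        n_ancestral=4,
        n_clade_shared=8,
        n_lineage_unique=5,
        seed=7,
    )
    return simulate_scenario(cfg)
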