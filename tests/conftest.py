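import pytest

from supermhc import KernelEngine, label_supertypes, make_world
from supermhc.substitution import load_default_model


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def engine():
    """One shared kernel engine so string-pair evaluations are cached
    across the whole session."""
    return KernelEngine()


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world: 4 supertypes x 3 alleles x 40 peptides,
    short chains, low noise."""
    return make_world(
        n_supertypes=4, alleles_per_supertype=3, n_peptides_per_allele=40,
        chain_length=30, mutation_rate=0.05, noise_sd=0.05, seed=7,
    )


def truth_assignment(world):
    """SupertypeAssignment built from the planted partition."""
    by_s = {}
    for mol, s in world.truth_partition.items():
        by_s.setdefault(s, []).append(mol)
    partition = [sorted(v) for v in by_s.values()]
    return label_supertypes(partition, world.isotype_of())


@pytest.fixture(scope="session")
def small_world_assignment(small_world):
    return truth_assignment(small_world)
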