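import numpy as np
import pytest

from metafid.community_sampler import CommunityProfile, GenomeSet, sample_reads
from metafid.fixtures import FixtureSpec, make_toy_genomes, make_toy_taxonomy


@pytest.fixture(scope="session")
def shared_block_genomes():
    """Three 3 kb genomes; G0 and G1 share one identical 300 bp block."""
    gs, registry = make_toy_genomes(
        FixtureSpec(
            n_genomes=3, genome_length=3000,
            shared_blocks=[((0, 1), 300)], seed=11,
        )
    )
    return gs, registry


@pytest.fixture(scope="session")
def toy_reads(shared_block_genomes):
    gs, _ = shared_block_genomes
    profile = CommunityProfile(
        entries=[("G0", 1.0), ("G1", 1.0), ("G2", 1.0)], read_length=100
    )
    reads = sample_reads(gs, profile, seed=7, find_alt_sites=True)
    return gs, profile, reads


@pytest.fixture(scope="session")
def toy_taxonomy():
    return make_toy_taxonomy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
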