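import numpy as np
import pytest

import juglandiv as jd


@pytest.fixture(scope="session")
def small_genome():
    """30 kb diploid genome at 1% heterozygosity."""
    return jd.simulate_diploid_genome(30_000, 0.01, seed=101)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    """80x reads with 0.5% error from the small genome."""
    return jd.simulate_reads(small_genome, depth=80, read_len=150, err=0.005, seed=102)


@pytest.fixture(scope="session")
def small_profile(small_reads):
    """(GenomeProfile, KmerHistogram, KmerDepthIndex) of the small read set."""
    return jd.profile_reads(small_reads, k=31)


@pytest.fixture(scope="session")
def quartet_tree_newick():
    return "((A:0.02,B:0.03):0.02,(C:0.01,D:0.04):0.03);"


@pytest.fixture
def rng():
    return np.random.default_rng(0)
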