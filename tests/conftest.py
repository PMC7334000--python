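import pytest

from fourcstab import (AnalysisConfig, digest, locate_viewpoint)
from fourcstab.simulate import SimConfig, simulate_genome

TOY_SEQ = "TTGATCAAGATCTT"  # GATC cuts at 2 and 8 -> fragments [0,2),[2,8),[8,14)


@pytest.fixture
def toy_fragments():
    from fourcstab import GenomeSeq
    return digest(GenomeSeq("toy", TOY_SEQ))


@pytest.fixture
def toy_viewpoint(toy_fragments):
    return locate_viewpoint(toy_fragments, "vp", "toy", 3)


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def sim_setup():
    """One digested synthetic chromosome shared across statistical tests."""
    sim = SimConfig(seed=11, chrom_length=600_000, viewpoint_pos=300_000)
    genome = simulate_genome(sim)
    fragments = digest(genome)
    viewpoint = locate_viewpoint(fragments, "vp", sim.chrom, sim.viewpoint_pos)
    return sim, genome, fragments, viewpoint
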