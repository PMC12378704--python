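import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from imprior.msa import extract_flanked, group_matches
from imprior.scanner import scan_motifs
from imprior.synthetic import FixtureSpec, simulate_genome


@pytest.fixture(scope="session")
def fixture_50():
    """Synthetic genome with 50 implants on a CCC/GGG-free background."""
    return simulate_genome(
        FixtureSpec(genome_length=35_000, n_implants=50, rng_seed=42)
    )


@pytest.fixture(scope="session")
def fixture_50_matches(fixture_50):
    return scan_motifs(fixture_50.genome)


@pytest.fixture(scope="session")
def fixture_alignment(fixture_50, fixture_50_matches):
    """Builtin alignment of the fixture's plus-strand group."""
    from imprior.msa import align_group

    flanked = [extract_flanked(m, fixture_50.genome) for m in fixture_50_matches]
    groups = group_matches(flanked)
    return align_group(groups[("chrS", "+")])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
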