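import numpy as np
import pytest

from metashot.fixtures import random_catalog
from metashot.reference import GenomeRecord, ReferenceCatalog
from metashot.simulate import CommunityDesign, simulate_reads


@pytest.fixture(scope="session")
def small_catalog():
    """Three random 20 kb genomes, one species each."""
    return random_catalog(3, 20_000, seed=11)


@pytest.fixture(scope="session")
def tiny_catalog():
    """Two short genomes for exhaustive-oracle alignment tests (<= 50 kb total)."""
    return random_catalog(2, 5_000, seed=7, name_prefix="Minima")


@pytest.fixture(scope="session")
def clean_reads(small_catalog):
    """Error-free 50 bp reads from the small catalog, 50 per genome."""
    design = CommunityDesign([(rec.record_id, 50) for rec in small_catalog])
    return simulate_reads(small_catalog, design, read_length=50, sub_rate=0.0, seed=3)


@pytest.fixture
def two_species_catalog():
    """Multi-chromosome genome plus a second species (hand-built)."""
    rng = np.random.default_rng(5)
    bases = "ACGT"
    mk = lambda n: "".join(bases[i] for i in rng.integers(0, 4, n))
    return ReferenceCatalog(
        [
            GenomeRecord("chrA1", "Alpha one X1", "Alpha one", "X1", sequence=mk(800)),
            GenomeRecord("chrA2", "Alpha one X1", "Alpha one", "X1", sequence=mk(600)),
            GenomeRecord("chrB", "Beta two Y9", "Beta two", "Y9", sequence=mk(900)),
        ]
    )
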