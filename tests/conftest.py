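"""Shared fixtures: small synthetic genomes, architectures, and cells."""

import numpy as np
import pytest

from snfold import synthetic
from snfold.genome import make_restriction_map


@pytest.fixture(scope="session")
def toy_rmap():
    """Restriction map with cuts {1000, 2000, 5000} on a 10-kb chromosome."""
    from snfold.genome import RestrictionMap

    return RestrictionMap({"chr1": [1000, 2000, 5000]}, {"chr1": 10_000})


@pytest.fixture(scope="session")
def small_genome():
    """60-kb random genome (GATC-rich enough for ~200 fragments)."""
    genome, seqs = synthetic.random_genome(
        chromosomes=(("chrS", 60_000),), seed=11
    )
    return genome, seqs, make_restriction_map(seqs, "GATC")


@pytest.fixture(scope="session")
def arch200():
    """200-bin architecture with default fly-like settings."""
    return synthetic.make_architecture(200, seed=1)


@pytest.fixture(scope="session")
def cell200(arch200):
    """One sparse cell sampled from arch200 (~6000 contacts)."""
    return synthetic.sample_cell_contacts(arch200, 6000, seed=2)


@pytest.fixture(scope="session")
def block_arch():
    """Ten equal 10-bin blocks with uniform stickiness (clean block model)."""
    return synthetic.GroundTruthArchitecture(
        n_bins=100,
        binsize=10_000,
        boundaries=np.arange(10, 100, 10),
        compartment=np.array(["A"] * 100),
        stickiness=np.ones(100),
        decay_exponent=1.5,
        enrichment=12.0,
    )
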