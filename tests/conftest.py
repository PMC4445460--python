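import numpy as np
import pytest

from yeastdmi.simcross import (
    GenomeMap,
    _YEAST_CHROMS,
    make_cross,
    two_locus_case_model,
    yeast_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bare_genome():
    """16 chromosomes, no markers (model loci get added by make_cross)."""
    return GenomeMap(chromosomes=tuple(_YEAST_CHROMS), markers=())


@pytest.fixture(scope="session")
def two_locus_model():
    return two_locus_case_model()


@pytest.fixture(scope="session")
def small_design(bare_genome, two_locus_model):
    """Two-marker design: just the driver and rescuer loci."""
    return make_cross(bare_genome, two_locus_model, seed=11)


@pytest.fixture(scope="session")
def dense_design(two_locus_model):
    """1 marker/kb genome-wide, the study's pooled-sequencing density."""
    return make_cross(yeast_genome(marker_spacing_bp=1000), two_locus_model,
                      seed=11)
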