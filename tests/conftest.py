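import numpy as np
import pytest

from nanofacet import crystal


@pytest.fixture(scope="session")
def gold():
    return crystal.LatticeSpec()


@pytest.fixture(scope="session")
def reference_particle(gold):
    """The gamma-ratio-0.96, 4 nm mass-matched particle."""
    return crystal.build_wulff_nanoparticle(gold, crystal.WulffSpec(0.96, 4.0))


@pytest.fixture(scope="session")
def small_particle(gold):
    """A small (~2 nm) particle for fast SASA and energy tests."""
    return crystal.build_wulff_nanoparticle(gold, crystal.WulffSpec(0.96, 2.0))


@pytest.fixture(scope="session")
def bare_sasa(reference_particle):
    from nanofacet import surface

    return surface.per_facet_sasa(reference_particle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
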