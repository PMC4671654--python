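import numpy as np
import pytest

from nphp1sv.locus import Genotype, build_reference_architecture, make_haplotype
from nphp1sv.simulate import SimParams, default_swai_sites


@pytest.fixture(scope="session")
def arch():
    return build_reference_architecture()


@pytest.fixture(scope="session")
def haps(arch):
    return {l: make_haplotype(l, arch) for l in
            ("H1", "H2", "H3", "H4", "H5", "H6", "H7")}


@pytest.fixture(scope="session")
def cn4_reference(haps):
    """NA10851-like universal aCGH reference: four 45 kb copies."""
    return Genotype.diploid(haps["H2"], haps["H2"])


@pytest.fixture(scope="session")
def swai_sites(arch):
    return default_swai_sites(arch)


@pytest.fixture()
def params():
    return SimParams(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160101)
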