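import numpy as np
import pytest

from splicefit.graph import Region
from splicefit.simulate import FixtureSpec, make_fixture
from splicefit.toy import make_cassette_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cassette3():
    return make_cassette_graph(3)


# a two-transcript cassette locus: tx1 includes the middle exon, tx2 skips it
FIXTURE_CHAINS = [
    [(100, 300), (400, 500), (600, 800)],
    [(100, 300), (600, 800)],
]
FIXTURE_REGION = Region("chrS", 0, 1000)


@pytest.fixture(scope="session")
def cassette_fixture(tmp_path_factory):
    """Deterministic synthetic SAM (2 samples) + GTF for the cassette locus."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(
        chrom="chrS",
        transcripts=FIXTURE_CHAINS,
        abundances=[[10.0, 5.0], [3.0, 12.0]],
        seed=3,
        dispersion=0.0,
    )
    sams, gtf = make_fixture(spec, out)
    return sams, gtf, spec
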