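import pytest
from hypothesis import settings

from mtxkit.peptides import Peptide
from mtxkit.simulate import MYOTOXIN3_SEQUENCE, make_fixture_suite

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def mtx3() -> Peptide:
    """The oxidized 45-residue crotamine-family peptide."""
    return Peptide(MYOTOXIN3_SEQUENCE, n_disulfides=3, name="myotoxin3")


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Full synthetic fixture set written once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixture_suite(outdir, seed=1234)
    return outdir, manifest
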