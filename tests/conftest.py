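import numpy as np
import pytest

from genedecay.reference_model import load_reference_bundle


@pytest.fixture(scope="session")
def bundle():
    return load_reference_bundle()


@pytest.fixture(scope="session")
def ref_cds(bundle):
    return bundle.cds


@pytest.fixture(scope="session")
def ref_locus(bundle):
    return bundle.locus


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
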