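import numpy as np
import pytest

from mirevo.synthetic_data import make_hairpin
from mirevo.target_scoring import DuplexAlignment, TargetSite, classify


@pytest.fixture
def perfect_template():
    """30-bp perfect stem, 6-nt loop, mature on the 3' arm."""
    return make_hairpin(30, 6, 0, 0, "3p", 1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def mk_site(mirna_id, gene_id, expectation=1.0, offset=(0, 22)):
    """Hand-built target site for network fixtures."""
    d = DuplexAlignment(mirna_id=mirna_id, gene_id=gene_id, offset=offset,
                        pairing="|" * 22, expectation=expectation)
    return TargetSite(duplex=d, stringency=classify(expectation) or "relaxed")
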