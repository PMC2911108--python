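import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barseq.catalog import Catalog, StrainRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TOY_TAGS = {
    # fixed, pairwise-distinct 20-mers for hand-built fixtures
    "u1": "ACGTACGTACGTACGTACGT",
    "d1": "TGCATGCATGCATGCATGCA",
    "u2": "AAAACCCCGGGGTTTTACGT",
    "d2": "TTTTGGGGCCCCAAAATGCA",
    "u3": "ACACACACACACACACACAC",
    "d3": "GTGTGTGTGTGTGTGTGTGT",
}


@pytest.fixture
def toy_records():
    return [
        StrainRecord("geneA", "P1-A01", "OK", TOY_TAGS["u1"], TOY_TAGS["d1"]),
        StrainRecord("geneB", "P1-A02", "W", TOY_TAGS["u2"], TOY_TAGS["d2"]),
        StrainRecord("geneC", "P1-A03", "OK", TOY_TAGS["u3"], TOY_TAGS["d3"]),
    ]


@pytest.fixture
def toy_catalog(toy_records):
    return Catalog.from_records(toy_records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
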