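import numpy as np
import pytest

from holoseq.io import GeneModel, GenomicInterval


@pytest.fixture
def two_exon_gene():
    """A + strand gene with exons [100,200) and [300,400), intron [200,300)."""
    iv = GenomicInterval("chr1", 100, 400, "+")
    return GeneModel(
        "gA",
        iv,
        (
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
        ),
    )


@pytest.fixture
def single_exon_gene():
    iv = GenomicInterval("chr1", 0, 1000, "+")
    return GeneModel("g1k", iv, (iv,))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
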