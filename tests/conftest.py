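import pytest

from splicetracks.regions import parse_region
from splicetracks.simulate import make_gene


@pytest.fixture
def gene():
    """Three 100 bp exons separated by 200 bp introns at chr1:10000,
    CDS covering the full span (300 nt = 100 aa)."""
    return make_gene([100, 100, 100], [200, 200], cds_span=(10_000, 10_700))


@pytest.fixture
def window():
    """Query window containing the whole fixture gene plus flanks."""
    return parse_region("chr1:9,901-10,800")
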