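import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from natpairs.types import GeneRecord, GeneTable  # noqa: E402


def gene(gid="g1", chrom="chr1", strand="+", start=100, end=500,
         biotype="protein_coding", symbol=None, source="src"):
    return GeneRecord(gid, symbol if symbol is not None else gid, chrom,
                      strand, start, end, biotype, source)


@pytest.fixture
def mkgene():
    return gene


@pytest.fixture
def small_table():
    """Divergent plus/minus pair (offset −333) and an unpaired gene."""
    return GeneTable.from_records([
        gene("s1", strand="+", start=1000, end=2000),
        gene("a1", strand="-", start=200, end=667, biotype="lncRNA"),
        gene("lone", chrom="chr2", strand="+", start=50, end=80),
    ])
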