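import numpy as np
import pytest

from neurocfdna.amplicon import (
    AmpliconReference,
    synthetic_chr3_amplicon,
    synthetic_chr19_amplicon,
)
from neurocfdna.reads import SequencedRead


@pytest.fixture(scope="session")
def toy_ref() -> AmpliconReference:
    """9 bp toy amplicon: CpGs at 1-based offsets 2 and 7, one non-CpG C
    at offset 6. Small enough that every call can be checked by hand."""
    return AmpliconReference(
        locus_id="toy", chrom="chrT", start=1, end=9,
        sequence="ACGATCCGT", cpg_positions=(2, 7),
    )


@pytest.fixture(scope="session")
def chr3_ref() -> AmpliconReference:
    return synthetic_chr3_amplicon()


@pytest.fixture(scope="session")
def chr19_ref() -> AmpliconReference:
    return synthetic_chr19_amplicon()


@pytest.fixture(scope="session")
def references(chr3_ref, chr19_ref):
    return [chr3_ref, chr19_ref]


def make_read(sequence: str, read_id: str = "r0", quality: int = 20) -> SequencedRead:
    return SequencedRead(read_id, sequence, (quality,) * len(sequence))


@pytest.fixture
def mk_read():
    return make_read
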