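import numpy as np
import pytest

from rnaedit.pileup import FilterThresholds
from rnaedit.seqio import AlignedRead, ReferenceGenome


def make_read(
    contig="chr1",
    pos=0,
    seq="ACGT",
    qual=30,
    mapq=60,
    strand="+",
    read_id="r1",
    cigar=None,
    sample_id=None,
):
    """Convenience constructor: uniform quality, gapless unless told otherwise."""
    if isinstance(qual, int):
        qual = [qual] * len(seq)
    if cigar is None:
        cigar = (("M", len(seq)),)
    return AlignedRead(
        read_id=read_id,
        contig=contig,
        pos=pos,
        strand=strand,
        sequence=seq,
        qualities=np.array(qual, dtype=np.uint8),
        mapq=mapq,
        cigar=tuple(cigar),
        sample_id=sample_id,
    )


@pytest.fixture
def thresholds():
    return FilterThresholds()


@pytest.fixture
def tiny_genome():
    return ReferenceGenome({"chr1": "ACGTACGTACGTACGTACGT", "chr2": "TTTTAAAACCCCGGGG"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
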