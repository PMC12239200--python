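import numpy as np
import pytest

from gametokit.core_io import GeneCopy


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_copy(
    copy_id="c1",
    genome_id="g1",
    locus="Ga1",
    role="silk",
    chrom="chr4",
    start=1000,
    end=None,
    strand="+",
    cds="ATGGCCAAA",
    cleave_offset=0,
):
    if end is None:
        end = start + len(cds) - 1
    return GeneCopy(
        copy_id=copy_id,
        genome_id=genome_id,
        locus=locus,
        role=role,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        cds=cds,
        cleave_offset=cleave_offset,
    )


@pytest.fixture
def gene_copy_factory():
    return make_copy
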