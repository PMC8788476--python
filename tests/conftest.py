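import pytest

from srnascout.alignments import AlignedRead, GenomicInterval


def _make_read(
    start,
    end,
    rid,
    chrom="chrT1",
    strand="+",
    multiplicity="unique",
    hit_count=None,
    cigar=None,
):
    if hit_count is None:
        hit_count = 1 if multiplicity == "unique" else 2
    return AlignedRead(
        read_id=rid,
        interval=GenomicInterval(chrom, start, end, strand),
        cigar=cigar or f"{end - start}M",
        hit_count=hit_count,
        multiplicity=multiplicity,
    )


@pytest.fixture
def make_read():
    """Factory for in-memory alignment records."""
    return _make_read


@pytest.fixture
def stack():
    """Factory for a homogeneous stack of identical reads."""

    def _stack(start, end, depth, prefix, **kwargs):
        return [
            _make_read(start, end, f"{prefix}_r{i:04d}", **kwargs)
            for i in range(depth)
        ]

    return _stack
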