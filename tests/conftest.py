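from __future__ import annotations

import pytest

from longiso.io_formats import GenomicInterval, TranscriptModel

MIRROR_L = 10_000_000


def mk_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    gene: str = "G",
    chrom: str = "chr1",
    support: int = 1,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        read_support=support,
    )


def mirror_transcript(t: TranscriptModel, flip_strand: bool, L: int = MIRROR_L) -> TranscriptModel:
    strand = t.strand
    if flip_strand:
        strand = "-" if strand == "+" else "+"
    exons = [(L - e.end, L - e.start) for e in t.exons]
    return mk_transcript(t.transcript_id, sorted(exons), strand, t.gene_id, t.chrom,
                         t.read_support)


@pytest.fixture
def simple_se_gene():
    """Three-exon isoform plus a two-exon isoform skipping the middle exon."""
    t1 = mk_transcript("T1", [(100, 200), (300, 400), (500, 600)])
    t2 = mk_transcript("T2", [(100, 200), (500, 600)])
    return [t1, t2]
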