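import pytest

from madsplice.models import (
    DomainAnnotation,
    GenomicInterval,
    PipelineConfig,
    ResidueInterval,
    TranscriptModel,
)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def toy_genome():
    # 9-nt chromosome used by the splicing examples
    return {"chr1": "ATGCCCAAA"}


@pytest.fixture
def two_exon_transcript():
    exons = [
        GenomicInterval("chr1", 0, 3, "+"),
        GenomicInterval("chr1", 6, 9, "+"),
    ]
    return TranscriptModel("t1", "g1", exons)


@pytest.fixture
def standard_domains():
    # the default synthetic MIKC layout: M 1-60, I 61-90, K 91-180, C 181-240
    return DomainAnnotation(
        protein_id="ref",
        m=ResidueInterval(1, 60),
        i=ResidueInterval(61, 90),
        k=ResidueInterval(91, 180),
        c=ResidueInterval(181, 240),
    )


def make_transcript(
    tid, exon_bounds, cds_bounds=(), chrom="chrT", strand="+", locus="locusT"
):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    cds = [GenomicInterval(chrom, s, e, strand) for s, e in cds_bounds]
    return TranscriptModel(tid, locus, exons, cds)
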