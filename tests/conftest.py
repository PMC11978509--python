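import pytest

from txbench.annotation import Annotation, Exon, Gene, Transcript


def make_tx(tid, gid, blocks, chrom="chr1", strand="+", biotype="protein_coding"):
    return Transcript(
        tid, gid, [Exon(chrom, s, e, strand) for s, e in blocks], biotype=biotype
    )


@pytest.fixture
def toy_annotation():
    """Three genes: a plus-strand gene with a subset isoform and an
    exon-skipping isoform, a minus-strand gene with a single-exon and a
    spliced transcript, and a single-isoform gene on another chromosome."""
    ga = Gene(
        "GA",
        [
            make_tx("TA1", "GA", [(100, 200), (300, 400), (500, 600)]),
            make_tx("TA2", "GA", [(100, 200), (300, 400)]),
            make_tx("TA3", "GA", [(100, 200), (500, 600)]),
        ],
        biotype="protein_coding",
    )
    gb = Gene(
        "GB",
        [
            make_tx("TB1", "GB", [(1000, 2000)], strand="-"),
            make_tx("TB2", "GB", [(1000, 1200), (1300, 1500)], strand="-"),
        ],
        biotype="lincRNA",
    )
    gc = Gene(
        "GC",
        [make_tx("TC1", "GC", [(50, 150), (250, 500)], chrom="chr2")],
        biotype="snoRNA",
    )
    return Annotation([ga, gb, gc])
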