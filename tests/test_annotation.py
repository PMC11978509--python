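"""Annotation model, GTF round-trips, coordinate conventions and the
annotation-matching / biotype filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txbench.annotation import (
    DEFAULT_BIOTYPES,
    Annotation,
    Exon,
    filter_biotypes,
    gene_length,
    junction_chain,
    match_annotations,
    project_to_genome,
    read_gtf,
    subset_isoforms,
    transcript_to_genome,
    write_gtf,
)
from .conftest import make_tx


TOY_GTF = """\
chr1\tsrc\tgene\t101\t600\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\tsrc\ttranscript\t101\t600\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t301\t600\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
"""


def test_read_gtf_counts_and_coordinates(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    ann = read_gtf(path)
    assert len(ann.genes) == 1
    assert len(ann.transcripts) == 2
    # 1-based closed [101, 200] becomes 0-based half-open [100, 200)
    e = ann.transcripts["T1"].exons[0]
    assert (e.start, e.end) == (100, 200)
    assert ann.genes["G1"].biotype == "protein_coding"


def test_gtf_round_trip_identity(tmp_path, toy_annotation):
    out = tmp_path / "rt.gtf"
    write_gtf(toy_annotation, out)
    reread = read_gtf(out)
    assert set(reread.genes) == set(toy_annotation.genes)
    assert set(reread.transcripts) == set(toy_annotation.transcripts)
    for tid, tx in toy_annotation.transcripts.items():
        other = reread.transcripts[tid]
        assert [(e.start, e.end) for e in tx.exons] == [
            (e.start, e.end) for e in other.exons
        ]
        assert other.strand == tx.strand
        assert junction_chain(other) == junction_chain(tx)


@pytest.mark.parametrize(
    "blocks,expected",
    [
        ([(100, 200)], ()),
        ([(100, 200), (300, 400), (500, 600)], ((200, 300), (400, 500))),
    ],
)
def test_junction_chain(blocks, expected):
    assert junction_chain(make_tx("T", "G", blocks)) == expected


def test_junction_chain_strand_independent():
    plus = make_tx("Tp", "G", [(100, 200), (300, 400), (500, 600)], strand="+")
    minus = make_tx("Tm", "G", [(100, 200), (300, 400), (500, 600)], strand="-")
    assert junction_chain(plus) == junction_chain(minus)


def test_match_annotations(toy_annotation):
    catalog = {"TA1", "TA2", "TA3", "TB1", "TB2"}  # TC1 missing
    filtered, removed = match_annotations(toy_annotation, catalog)
    assert removed == 1
    assert "GC" not in filtered.genes
    # idempotent, and removed + retained = input
    again, removed2 = match_annotations(filtered, catalog)
    assert removed2 == 0
    assert len(filtered.genes) + removed == len(toy_annotation.genes)

    _, removed_all = match_annotations(toy_annotation, set())
    assert removed_all == len(toy_annotation.genes)


def test_match_annotations_partial_gene_removed(toy_annotation):
    # one of GA's transcripts absent -> whole gene removed
    filtered, removed = match_annotations(
        toy_annotation, {"TA1", "TA2", "TB1", "TB2", "TC1"}
    )
    assert removed == 1 and "GA" not in filtered.genes


def test_filter_biotypes(toy_annotation):
    kept, removed = filter_biotypes(toy_annotation, allowed={"protein_coding"})
    assert removed == 2 and set(kept.genes) == {"GA"}
    kept2, removed2 = filter_biotypes(toy_annotation, allowed=DEFAULT_BIOTYPES)
    assert removed2 == 1 and "GB" in kept2.genes  # lincRNA retained, snoRNA dropped
    all_bt = {g.biotype for g in toy_annotation.genes.values()}
    _, removed3 = filter_biotypes(toy_annotation, allowed=all_bt)
    assert removed3 == 0


def test_gene_length_is_max_isoform(toy_annotation):
    assert gene_length(toy_annotation.genes["GA"]) == 300
    assert gene_length(toy_annotation.genes["GC"]) == 350


@pytest.mark.parametrize(
    "strand,pos,expected",
    [("+", 0, 100), ("+", 99, 199), ("-", 0, 199), ("-", 99, 100)],
)
def test_transcript_to_genome_single_exon(strand, pos, expected):
    tx = make_tx("T", "G", [(100, 200)], strand=strand)
    assert transcript_to_genome(tx, pos) == expected


@pytest.mark.parametrize("strand", ["+", "-"])
def test_transcript_to_genome_bijection_brute_force(strand):
    tx = make_tx("T", "G", [(100, 180), (240, 300), (400, 450)], strand=strand)
    mapped = [transcript_to_genome(tx, p) for p in range(tx.length)]
    exonic = sorted(p for e in tx.exons for p in range(e.start, e.end))
    assert sorted(mapped) == exonic  # bijection onto the exonic base set
    if strand == "-":
        assert mapped[0] == 449  # 5' end of a minus-strand transcript


@pytest.mark.parametrize("strand", ["+", "-"])
def test_project_to_genome_matches_per_base_map(strand):
    tx = make_tx("T", "G", [(10, 40), (60, 90), (120, 130)], strand=strand)
    for start in range(0, tx.length - 1, 7):
        for end in (start + 1, min(start + 25, tx.length)):
            blocks = project_to_genome(tx, start, end)
            covered = sorted(p for s, e in blocks for p in range(s, e))
            expected = sorted(transcript_to_genome(tx, q) for q in range(start, end))
            assert covered == expected


def test_transcript_to_genome_out_of_range():
    tx = make_tx("T", "G", [(0, 10)])
    with pytest.raises(ValueError):
        transcript_to_genome(tx, 10)


def test_subset_isoform_detection(toy_annotation):
    assert subset_isoforms(toy_annotation.genes["GA"]) == {"TA2"}
    assert subset_isoforms(toy_annotation.genes["GB"]) == set()


@settings(derandomize=True, max_examples=50)
@given(
    widths=st.lists(st.integers(10, 100), min_size=1, max_size=6),
    gaps=st.lists(st.integers(5, 50), min_size=5, max_size=5),
    shift=st.integers(0, 10_000),
)
def test_junction_chain_length_property(widths, gaps, shift):
    """Chain length is always exon count - 1 and shifts translate chains."""
    pos = shift
    blocks = []
    for i, w in enumerate(widths):
        if i:
            pos += gaps[(i - 1) % len(gaps)]
        blocks.append((pos, pos + w))
        pos += w
    tx = make_tx("T", "G", blocks)
    chain = junction_chain(tx)
    assert len(chain) == len(widths) - 1
    shifted = make_tx("T", "G", [(s + 5, e + 5) for s, e in blocks])
    assert junction_chain(shifted) == tuple((d + 5, a + 5) for d, a in chain)


def test_empty_annotation_rejected(toy_annotation):
    with pytest.raises(ValueError):
        match_annotations(Annotation([]), {"x"})


def test_exon_invariants():
    with pytest.raises(ValueError):
        Exon("chr1", 100, 100, "+")
    with pytest.raises(ValueError):
        make_tx("T", "G", [(0, 100), (50, 150)])
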