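"""Read classification against the annotation: full-splice-match vs
partial semantics, read classes and assignment ambiguity."""

import pytest

from txbench.annotation import Annotation
from txbench.classify import (
    FULL_SPLICE_MATCH,
    PARTIAL,
    UNASSIGNED,
    ReadAlignment,
    build_read_classes,
    classify_read,
    junctions_per_read,
    unique_assignment_stats,
)
from .conftest import make_tx


def gread(rid, blocks, chrom="chr1"):
    return ReadAlignment(rid, "genome", chrom, blocks)


def test_full_splice_match_exact_chain(toy_annotation):
    read = gread("r1", [(120, 200), (300, 400), (500, 580)])
    label, compat = classify_read(read, toy_annotation)
    assert label == FULL_SPLICE_MATCH and compat == {"TA1"}


def test_partial_consecutive_subchain(toy_annotation):
    # chain = first junction of TA1 only; equals TA2's complete chain
    read = gread("r2", [(150, 200), (300, 350)])
    label, compat = classify_read(read, toy_annotation)
    assert label == FULL_SPLICE_MATCH and compat == {"TA2"}
    # a spliced read matching TA1's second junction only: partial to TA1
    read = gread("r3", [(350, 400), (500, 550)])
    label, compat = classify_read(read, toy_annotation)
    assert label == PARTIAL and compat == {"TA1"}


def test_unknown_junction_unassigned(toy_annotation):
    label, compat = classify_read(gread("r4", [(150, 250), (320, 380)]), toy_annotation)
    assert label == UNASSIGNED and compat == frozenset()


def test_junction_free_reads(toy_annotation):
    # contained in single-exon transcript TB1 -> FSM
    label, compat = classify_read(gread("r5", [(1100, 1180)]), toy_annotation)
    assert label == FULL_SPLICE_MATCH and compat == {"TB1"}
    # inside GA's first exon -> partial to all three multi-exon isoforms
    label, compat = classify_read(gread("r6", [(110, 190)]), toy_annotation)
    assert label == PARTIAL and compat == {"TA1", "TA2", "TA3"}
    # spliced-only mode leaves junction-free reads unassigned
    label, _ = classify_read(gread("r7", [(110, 190)]), toy_annotation, spliced_only=True)
    assert label == UNASSIGNED


def test_unknown_chromosome_is_unassigned_not_error(toy_annotation):
    label, compat = classify_read(gread("r8", [(0, 50)], chrom="chrZ"), toy_annotation)
    assert label == UNASSIGNED and compat == frozenset()


def test_transcriptome_space_equivalent_to_genome_space(toy_annotation):
    # full-length read on TA1 in transcript coordinates
    read = ReadAlignment("t1", "transcriptome", "TA1", [(0, 300)])
    label, compat = classify_read(read, toy_annotation)
    assert label == FULL_SPLICE_MATCH and compat == {"TA1"}
    # 3' half of minus-strand TB2 projects across its junction
    read = ReadAlignment("t2", "transcriptome", "TB2", [(0, 300)])
    label, compat = classify_read(read, toy_annotation)
    assert label == FULL_SPLICE_MATCH and compat == {"TB2"}


def test_junctions_per_read(toy_annotation):
    assert junctions_per_read(gread("r", [(0, 100)])) == 0
    assert junctions_per_read(gread("r", [(0, 100), (200, 300), (400, 450)])) == 2
    read = ReadAlignment("t", "transcriptome", "TA1", [(0, 300)])
    assert junctions_per_read(read, toy_annotation) == 2


def test_translation_invariance(toy_annotation):
    """Shifting annotation and reads by a constant changes no label."""
    shift = 10_000
    shifted_ann = Annotation(
        [
            type(g)(
                g.id,
                [
                    make_tx(
                        t.id, g.id,
                        [(e.start + shift, e.end + shift) for e in t.exons],
                        chrom=t.chrom, strand=t.strand,
                    )
                    for t in g.transcripts
                ],
                g.biotype,
            )
            for g in toy_annotation.genes.values()
        ]
    )
    cases = [
        [(120, 200), (300, 400), (500, 580)],
        [(350, 400), (500, 550)],
        [(110, 190)],
        [(1100, 1180)],
    ]
    for blocks in cases:
        base = classify_read(gread("r", blocks), toy_annotation)
        moved = classify_read(
            gread("r", [(s + shift, e + shift) for s, e in blocks]), shifted_ann
        )
        assert base == moved


def test_build_read_classes_grouping(toy_annotation):
    reads = [gread(f"r{i}", [(120, 200), (300, 400), (500, 580)]) for i in range(5)]
    classes = build_read_classes(reads, toy_annotation)
    assert len(classes) == 1
    (c,) = classes
    assert c.count == 5 and c.compatible == {"TA1"}
    assert c.width == 580 - 120

    reads.append(gread("alt", [(150, 200), (300, 350)]))
    classes = build_read_classes(reads, toy_annotation)
    assert len(classes) == 2
    assert sum(c.count for c in classes) == 6


def test_class_compatibility_matches_per_read_classification(toy_annotation):
    """Every class's compatible set equals the per-read brute force of each
    of its members."""
    reads = [
        gread("a", [(120, 200), (300, 400), (500, 580)]),
        gread("b", [(110, 200), (300, 400), (500, 590)]),
        gread("c", [(350, 400), (500, 550)]),
        gread("d", [(110, 190)]),
        gread("e", [(1100, 1180)]),
    ]
    per_read = {r.read_id: classify_read(r, toy_annotation) for r in reads}
    classes = build_read_classes(reads, toy_annotation)
    assert sum(c.count for c in classes) == len(
        [r for r in reads if per_read[r.read_id][0] != UNASSIGNED]
    )
    for c in classes:
        matching = [
            rid for rid, (label, compat) in per_read.items()
            if label == c.label and compat == c.compatible
        ]
        assert len(matching) >= c.count >= 1


def test_unique_assignment_stats(toy_annotation):
    reads = [
        gread("u1", [(120, 200), (300, 400), (500, 580)]),  # unique TA1
        gread("u2", [(1100, 1180)]),  # unique TB1
        gread("m1", [(110, 190)]),  # ambiguous over 3 isoforms
    ]
    classes = build_read_classes(reads, toy_annotation)
    hist, unique_fraction = unique_assignment_stats(classes)
    assert hist == {1: 2, 3: 1}
    assert unique_fraction == pytest.approx(2 / 3)


def test_fsm_implies_nonempty_unassigned_implies_empty(toy_annotation):
    for blocks in ([(120, 200), (300, 400), (500, 580)], [(0, 40)], [(110, 190)]):
        label, compat = classify_read(gread("r", blocks), toy_annotation)
        if label == UNASSIGNED:
            assert not compat
        else:
            assert compat
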