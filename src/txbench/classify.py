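"""Read-to-transcript classification.

A read is a *full splice match* (FSM) when its splice-junction chain exactly
equals the complete junction chain of an annotated transcript; *partial*
when its chain is a non-empty consecutive sub-chain of at least one
transcript chain (without equalling any), or when it is junction-free and
contained within one exon of a multi-exon transcript; *unassigned*
otherwise. Junction-free reads contained in a single-exon transcript count
as FSM to it. Transcriptome-space alignments are projected to genome space
so both input kinds share one code path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .annotation import Annotation, project_to_genome

__all__ = [
    "ReadAlignment",
    "ReadClass",
    "classify_read",
    "junctions_per_read",
    "build_read_classes",
    "unique_assignment_stats",
    "FULL_SPLICE_MATCH",
    "PARTIAL",
    "UNASSIGNED",
]

FULL_SPLICE_MATCH = "full_splice_match"
PARTIAL = "partial"
UNASSIGNED = "unassigned"


@dataclass
class ReadAlignment:
    """One aligned read.

    ``space`` is ``"genome"`` (target = chromosome, blocks genomic) or
    ``"transcriptome"`` (target = transcript id, blocks in transcript
    coordinates, deletions merged into blocks). ``source`` optionally tags
    the true transcript of origin for simulated reads; no analysis stage
    reads it.
    """

    read_id: str
    space: str
    target: str
    blocks: list[tuple[int, int]]
    source: str | None = None

    def __post_init__(self) -> None:
        if self.space not in ("genome", "transcriptome"):
            raise ValueError(f"unknown alignment space {self.space!r}")
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping blocks in read {self.read_id}")
        if any(s >= e for s, e in self.blocks):
            raise ValueError(f"empty block in read {self.read_id}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def mapped_length(self) -> int:
        """Alignment span on the target (end - start)."""
        return self.end - self.start


@dataclass
class ReadClass:
    """Equivalence class of reads sharing chromosome, junction chain,
    label and compatible-transcript set."""

    chrom: str
    chain: tuple[tuple[int, int], ...]
    label: str
    count: int
    compatible: frozenset[str]
    start: int
    end: int

    @property
    def width(self) -> int:
        """Span of the class's exonic extent on the genome."""
        return self.end - self.start

    @property
    def exonic_width(self) -> int:
        """Span minus the class's intron gaps (summed block widths)."""
        return self.width - sum(a - d for d, a in self.chain)


def genome_blocks(
    read: ReadAlignment, annotation: Annotation
) -> tuple[str, list[tuple[int, int]]]:
    """Return (chromosome, genomic blocks) for a read in either space."""
    if read.space == "genome":
        return read.target, read.blocks
    tx = annotation.transcripts.get(read.target)
    if tx is None:
        raise KeyError(f"read {read.read_id} aligned to unknown transcript {read.target}")
    blocks: list[tuple[int, int]] = []
    for s, e in read.blocks:
        blocks.extend(project_to_genome(tx, s, e))
    blocks.sort()
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return tx.chrom, merged


def _chain_of(blocks: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    return tuple((a[1], b[0]) for a, b in zip(blocks, blocks[1:]))


def _is_consecutive_subchain(
    sub: tuple[tuple[int, int], ...], chain: tuple[tuple[int, int], ...]
) -> bool:
    n, m = len(sub), len(chain)
    if n > m:
        return False
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


def classify_read(
    read: ReadAlignment,
    annotation: Annotation,
    spliced_only: bool = False,
) -> tuple[str, frozenset[str]]:
    """Classify one read; returns (label, compatible transcript ids).

    ``spliced_only`` restricts FSM/partial labels to spliced reads,
    leaving junction-free reads unassigned.
    """
    try:
        chrom, blocks = genome_blocks(read, annotation)
    except KeyError:
        return UNASSIGNED, frozenset()
    chain = _chain_of(blocks)
    start, end = blocks[0][0], blocks[-1][1]

    if chain:
        fsm = annotation.chain_index.get((chrom, chain))
        if fsm:
            return FULL_SPLICE_MATCH, frozenset(fsm)
        candidates: set[str] = set()
        for j in chain:
            candidates |= annotation.junction_index.get((chrom, j), set())
        partial = frozenset(
            tid
            for tid in candidates
            if _is_consecutive_subchain(chain, annotation.chains[tid])
            and start >= annotation.transcripts[tid].start
            and end <= annotation.transcripts[tid].end
        )
        if partial:
            return PARTIAL, partial
        return UNASSIGNED, frozenset()

    if spliced_only:
        return UNASSIGNED, frozenset()

    fsm_hits: set[str] = set()
    partial_hits: set[str] = set()
    for tid in annotation.transcripts_overlapping(chrom, start, end):
        tx = annotation.transcripts[tid]
        contained = any(e.start <= start and end <= e.end for e in tx.exons)
        if not contained:
            continue
        if len(tx.exons) == 1:
            fsm_hits.add(tid)
        else:
            partial_hits.add(tid)
    if fsm_hits:
        return FULL_SPLICE_MATCH, frozenset(fsm_hits)
    if partial_hits:
        return PARTIAL, frozenset(partial_hits)
    return UNASSIGNED, frozenset()


def junctions_per_read(read: ReadAlignment, annotation: Annotation | None = None) -> int:
    """Number of splice junctions covered by the read (block count - 1
    after genome projection)."""
    if read.space == "genome" or annotation is None:
        return len(read.blocks) - 1
    _, blocks = genome_blocks(read, annotation)
    return len(blocks) - 1


def build_read_classes(
    reads: list[ReadAlignment],
    annotation: Annotation,
    spliced_only: bool = False,
    keep_unassigned: bool = False,
) -> list[ReadClass]:
    """Group classified reads into read classes.

    The grouping key is (chromosome, junction chain, label, compatible set),
    so every class's compatibility equals that of each of its member reads.
    Class width is the span of the class's exonic extent.
    """
    acc: dict[tuple, list[int]] = {}
    for read in reads:
        label, compatible = classify_read(read, annotation, spliced_only=spliced_only)
        if label == UNASSIGNED and not keep_unassigned:
            continue
        try:
            chrom, blocks = genome_blocks(read, annotation)
        except KeyError:
            continue
        key = (chrom, _chain_of(blocks), label, compatible)
        entry = acc.setdefault(key, [0, blocks[0][0], blocks[-1][1]])
        entry[0] += 1
        entry[1] = min(entry[1], blocks[0][0])
        entry[2] = max(entry[2], blocks[-1][1])
    return [
        ReadClass(chrom, chain, label, count, compatible, start, end)
        for (chrom, chain, label, compatible), (count, start, end) in acc.items()
    ]


def unique_assignment_stats(classes: list[ReadClass]) -> tuple[Counter, float]:
    """Histogram of compatible-set sizes weighted by read count, and the
    fraction of reads uniquely assigned (|compatible| == 1)."""
    hist: Counter = Counter()
    for c in classes:
        hist[len(c.compatible)] += c.count
    total = sum(hist.values())
    unique_fraction = hist.get(1, 0) / total if total else float("nan")
    return hist, unique_fraction


def read_bam_alignments(path: str, transcriptome: bool = True) -> list[ReadAlignment]:
    """Read primary alignments from BAM/SAM into ReadAlignment records.

    Secondary and supplementary alignments are skipped. Deletions are merged
    into blocks (only N introduces a new block), matching the coverage
    convention used throughout.
    """
    import pysam

    reads: list[ReadAlignment] = []
    space = "transcriptome" if transcriptome else "genome"
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks: list[tuple[int, int]] = []
            pos = aln.reference_start
            cur_start = pos
            for op, length in aln.cigartuples or []:
                if op in (0, 2, 7, 8):  # M, D, =, X consume reference
                    pos += length
                elif op == 3:  # N: splice gap ends the block
                    blocks.append((cur_start, pos))
                    pos += length
                    cur_start = pos
            if pos > cur_start:
                blocks.append((cur_start, pos))
            if blocks:
                reads.append(
                    ReadAlignment(aln.query_name, space, aln.reference_name, blocks)
                )
    return reads
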