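"""Gene/transcript annotation model and GTF I/O.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the 1-based closed convention. Junction identity is the genomic
``(donor_end, acceptor_start)`` pair and junction chains are kept in
ascending genomic order regardless of strand, matching how splice-junction
equality is evaluated from read alignments.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "Exon",
    "Transcript",
    "Gene",
    "Annotation",
    "read_gtf",
    "write_gtf",
    "junction_chain",
    "match_annotations",
    "filter_biotypes",
    "gene_length",
    "transcript_to_genome",
    "project_to_genome",
    "read_transcript_fasta",
    "DEFAULT_BIOTYPES",
]

#: Ensembl biotype labels corresponding to protein-coding genes, antisense
#: RNAs, long intergenic noncoding RNAs, noncoding RNAs and macro lncRNAs.
DEFAULT_BIOTYPES = frozenset(
    {"protein_coding", "antisense", "lincRNA", "non_coding", "macro_lncRNA"}
)


@dataclass(frozen=True)
class Exon:
    """One exon, 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    id: str
    gene_id: str
    exons: list[Exon]
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in transcript {self.id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.width for e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


@dataclass
class Gene:
    id: str
    transcripts: list[Transcript] = field(default_factory=list)
    biotype: str = ""

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def junction_chain(transcript: Transcript) -> tuple[tuple[int, int], ...]:
    """Ordered (donor_end, acceptor_start) pairs between consecutive exons.

    The chain is in ascending genomic order on both strands; single-exon
    transcripts yield an empty chain.
    """
    exons = transcript.exons
    return tuple((a.end, b.start) for a, b in zip(exons, exons[1:]))


def gene_length(gene: Gene) -> int:
    """Gene length, defined as the maximum isoform length."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id} has no transcripts")
    return max(t.length for t in gene.transcripts)


class Annotation:
    """Container indexing genes, transcripts, junction chains and extents."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValueError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
            for t in g.transcripts:
                if t.id in self.transcripts:
                    raise ValueError(f"duplicate transcript id {t.id}")
                if t.gene_id != g.id:
                    raise ValueError(
                        f"transcript {t.id} gene_id {t.gene_id} != {g.id}"
                    )
                self.transcripts[t.id] = t
        self._build_indexes()

    def _build_indexes(self) -> None:
        self.chains: dict[str, tuple[tuple[int, int], ...]] = {}
        self.chain_index: dict[tuple[str, tuple], list[str]] = {}
        self.junction_index: dict[tuple[str, tuple[int, int]], set[str]] = {}
        self._extent_trees: dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            chain = junction_chain(t)
            self.chains[t.id] = chain
            if chain:
                self.chain_index.setdefault((t.chrom, chain), []).append(t.id)
            for j in chain:
                self.junction_index.setdefault((t.chrom, j), set()).add(t.id)
            tree = self._extent_trees.setdefault(t.chrom, IntervalTree())
            tree.addi(t.start, t.end, t.id)

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._extent_trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def gene_of(self, transcript_id: str) -> Gene:
        return self.genes[self.transcripts[transcript_id].gene_id]


def read_gtf(path: str | Path) -> Annotation:
    """Read an Ensembl-dialect GTF into an :class:`Annotation`.

    Accepts gene/transcript/exon features with ``gene_id`` /
    ``transcript_id`` attributes (``gene_biotype`` captured when present);
    converts 1-based closed GTF coordinates to the internal 0-based
    half-open convention.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc

    biotypes: dict[str, str] = {}
    for feat in db.features_of_type(("gene", "transcript")):
        gid = feat.attributes.get("gene_id", [None])[0]
        bt = feat.attributes.get("gene_biotype", [""])[0]
        if gid and bt:
            biotypes.setdefault(gid, bt)

    tx_exons: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ValueError(f"exon without transcript_id at {feat.seqid}:{feat.start}")
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValueError(f"exon without gene_id at {feat.seqid}:{feat.start}")
        tid = tids[0]
        tx_gene[tid] = gid
        tx_exons.setdefault(tid, []).append(
            Exon(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )

    genes: dict[str, Gene] = {}
    for tid, exons in tx_exons.items():
        gid = tx_gene[tid]
        gene = genes.setdefault(gid, Gene(gid, [], biotypes.get(gid, "")))
        gene.transcripts.append(
            Transcript(tid, gid, exons, biotype=biotypes.get(gid, ""))
        )
    return Annotation(genes.values())


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write gene/transcript/exon features, 1-based closed coordinates."""
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            attrs = f'gene_id "{gene.id}";'
            if gene.biotype:
                attrs += f' gene_biotype "{gene.biotype}";'
            fh.write(
                f"{gene.chrom}\ttxbench\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.transcripts[0].strand}\t.\t{attrs}\n"
            )
            for t in gene.transcripts:
                tattrs = f'gene_id "{gene.id}"; transcript_id "{t.id}";'
                if gene.biotype:
                    tattrs += f' gene_biotype "{gene.biotype}";'
                fh.write(
                    f"{t.chrom}\ttxbench\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\ttxbench\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{tattrs}\n"
                    )


def match_annotations(
    annotation: Annotation, transcript_catalog: set[str] | frozenset[str]
) -> tuple[Annotation, int]:
    """Keep only genes whose transcripts are all present in the catalog.

    The catalog is typically the set of transcript ids present in the
    transcriptome FASTA; genes with any transcript missing are removed
    entirely and the count of removed genes is returned.
    """
    if not annotation.genes:
        raise ValueError("empty annotation")
    kept: list[Gene] = []
    removed = 0
    for gene in annotation.genes.values():
        if all(t.id in transcript_catalog for t in gene.transcripts):
            kept.append(gene)
        else:
            removed += 1
    return Annotation(kept), removed


def filter_biotypes(
    annotation: Annotation, allowed: Iterable[str] = DEFAULT_BIOTYPES
) -> tuple[Annotation, int]:
    """Remove genes whose biotype is not in ``allowed``; return removed count."""
    allowed = frozenset(allowed)
    kept = [g for g in annotation.genes.values() if g.biotype in allowed]
    removed = len(annotation.genes) - len(kept)
    return Annotation(kept), removed


def transcript_to_genome(transcript: Transcript, pos: int) -> int:
    """Genomic coordinate of transcript-space offset ``pos`` (5'->3')."""
    if not 0 <= pos < transcript.length:
        raise ValueError(f"position {pos} outside transcript of length {transcript.length}")
    exons = transcript.exons if transcript.strand == "+" else transcript.exons[::-1]
    for e in exons:
        if pos < e.width:
            return e.start + pos if transcript.strand == "+" else e.end - 1 - pos
        pos -= e.width
    raise AssertionError("unreachable")


def project_to_genome(
    transcript: Transcript, start: int, end: int
) -> list[tuple[int, int]]:
    """Project a transcript-space half-open interval onto genomic blocks.

    Returns sorted, non-overlapping 0-based half-open genomic intervals.
    """
    if not (0 <= start < end <= transcript.length):
        raise ValueError(f"invalid transcript interval [{start}, {end})")
    blocks: list[tuple[int, int]] = []
    exons = transcript.exons if transcript.strand == "+" else transcript.exons[::-1]
    offset = 0
    for e in exons:
        lo = max(start, offset)
        hi = min(end, offset + e.width)
        if lo < hi:
            if transcript.strand == "+":
                blocks.append((e.start + (lo - offset), e.start + (hi - offset)))
            else:
                blocks.append((e.end - (hi - offset), e.end - (lo - offset)))
        offset += e.width
    blocks.sort()
    return blocks


def subset_isoforms(gene: Gene) -> set[str]:
    """Transcript ids whose junction chain is a strict consecutive
    sub-chain of a sibling isoform's chain (subset isoforms)."""
    chains = {t.id: junction_chain(t) for t in gene.transcripts}
    out: set[str] = set()
    for tid, chain in chains.items():
        if not chain:
            continue
        for oid, other in chains.items():
            if oid == tid or len(other) <= len(chain):
                continue
            n, m = len(chain), len(other)
            if any(other[i : i + n] == chain for i in range(m - n + 1)):
                out.add(tid)
                break
    return out


def read_transcript_fasta(
    path: str | Path, strip_versions: bool = False
) -> dict[str, str]:
    """Read transcript sequences keyed by id.

    ``strip_versions`` drops a trailing ``.N`` version suffix from each id so
    catalogs built from versioned FASTA headers can be matched against
    unversioned GTF transcript ids.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.rsplit(".", 1)[0] if strip_versions and "." in rec.id else rec.id
        seqs[name] = str(rec.seq).upper()
    return seqs
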