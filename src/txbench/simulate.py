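"""Seeded synthetic transcriptome, expression and read-population generator.

Emulates the protocol behaviours of long- and short-read RNA-seq libraries:
3'-anchored truncation for direct-RNA-like reads, mostly full-length
PCR-cDNA-like reads with concentration bias toward highly expressed genes,
short-transcript depletion for IsoSeq-like reads, uniformly positioned
fixed-length fragments for short-read-like data, and spike-in mixes of
known relative concentration. Genes may contain a *subset isoform* — one
whose junction chain is a strict consecutive sub-chain of a longer
isoform's — the structure behind the internal first/last-exon pattern of
major-isoform disagreement.

All randomness flows from one master seed; per-stage streams are derived
with fixed offsets so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import Annotation, Exon, Gene, Transcript, junction_chain, subset_isoforms
from .classify import ReadAlignment

__all__ = [
    "SimulationConfig",
    "ProtocolProfile",
    "GroundTruth",
    "PROTOCOL_PROFILES",
    "stage_rng",
    "generate_annotation",
    "generate_expression",
    "simulate_long_reads",
    "simulate_short_reads",
    "generate_spikein",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Fixed per-stage offsets of the seed scheme.
_STAGE_OFFSETS = {
    "annotation": 11,
    "expression": 23,
    "long_reads": 37,
    "short_reads": 53,
    "spikein": 71,
}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Derive the RNG stream for a pipeline stage from the master seed."""
    return np.random.default_rng([_STAGE_OFFSETS[stage], index, seed])


@dataclass(frozen=True)
class ProtocolProfile:
    """Read-population behaviour of one library preparation protocol."""

    name: str
    truncation_prob: float  # probability a read is 3'-truncated at the 5' end
    three_prime_anchored: bool = True
    pcr_bias_epsilon: float = 0.0  # sampling weight CPM^(1+eps)
    length_midpoint: float | None = None  # logistic depletion of short transcripts


#: Study conditions: direct-RNA-like reads truncate often (pore ejection,
#: 3'-anchored because sequencing starts at the poly(A) tail); direct-cDNA
#: less so; PCR-cDNA is mostly full length but concentration-biased toward
#: top-expressed genes; IsoSeq is full length with short transcripts depleted.
PROTOCOL_PROFILES: dict[str, ProtocolProfile] = {
    "dRNA-like": ProtocolProfile("dRNA-like", truncation_prob=0.4),
    "dcDNA-like": ProtocolProfile("dcDNA-like", truncation_prob=0.3),
    "PCR-cDNA-like": ProtocolProfile(
        "PCR-cDNA-like", truncation_prob=0.15, pcr_bias_epsilon=0.1
    ),
    "IsoSeq-like": ProtocolProfile(
        "IsoSeq-like", truncation_prob=0.0, length_midpoint=1000.0
    ),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the desk-scale
    conditions used throughout the analyses."""

    n_genes: int = 200
    isoforms_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.4, 3: 0.3, 4: 0.1}
    )
    exons_per_transcript: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (60, 250)
    subset_isoform_fraction: float = 0.3
    subset_usage_multiplier: float = 0.005  # subset isoforms are truly minor
    gene_expr_mu: float = 3.0  # log-normal location on the CPM scale
    gene_expr_sigma: float = 1.5
    isoform_usage_concentration: float = 1.5  # symmetric Dirichlet
    replicate_sigma: float = 0.15  # log-normal replicate noise
    n_reads: int = 100_000
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        probs = np.array(list(self.isoforms_per_gene.values()), dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("isoforms_per_gene must be a proper distribution")
        for lo, hi in (self.exons_per_transcript, self.exon_length, self.intron_length):
            if lo < 1 or hi < lo:
                raise ValueError("infeasible length range")


@dataclass
class GroundTruth:
    """True per-sample transcript CPM, true major isoforms and spike-in
    expectations for a simulated dataset."""

    cpm: pd.DataFrame  # transcripts x samples, each column sums to 1e6
    major_isoform: pd.Series  # gene_id -> transcript id (argmax of mean CPM)
    spike_fractions: pd.Series | None = None


def _random_transcript_structure(
    rng: np.random.Generator, cfg: SimulationConfig, origin: int
) -> list[tuple[int, int]]:
    n_exons = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    exons = []
    pos = origin
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        width = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exons.append((pos, pos + width))
        pos += width
    return exons


def generate_annotation(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[Annotation, dict[str, str]]:
    """Generate a synthetic annotation and matching transcript sequences.

    Genes are laid out non-overlapping on one synthetic chromosome. With
    probability ``subset_isoform_fraction`` a multi-isoform gene carries a
    subset isoform: a consecutive exon sub-range of its first (longest)
    isoform, so its junction chain is a strict consecutive sub-chain.
    """
    seed = cfg.seed if seed is None else seed
    rng = stage_rng(seed, "annotation")
    k_choices = np.array(list(cfg.isoforms_per_gene.keys()))
    k_probs = np.array(list(cfg.isoforms_per_gene.values()), dtype=float)

    genes: list[Gene] = []
    pos = 1000
    chrom_len = 0
    exon_records: list[tuple[int, int]] = []
    for gi in range(cfg.n_genes):
        gid = f"G{gi:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.choice(k_choices, p=k_probs))
        parent = _random_transcript_structure(rng, cfg, pos)
        structures: list[list[tuple[int, int]]] = [parent]
        chains = {tuple(parent)}
        want_subset = (
            n_iso >= 2 and len(parent) >= 3 and rng.random() < cfg.subset_isoform_fraction
        )
        if want_subset:
            # consecutive sub-range dropping one terminal exon, so the subset
            # shares most of its parent's junctions (slowly identifiable for
            # fragment-length reads)
            if rng.random() < 0.5:
                sub = parent[1:]
            else:
                sub = parent[:-1]
            structures.append(sub)
            chains.add(tuple(sub))
        while len(structures) < n_iso and len(parent) >= 3:
            # exon-skipping variant of the parent
            keep = [
                e
                for k, e in enumerate(parent)
                if k in (0, len(parent) - 1) or rng.random() > 0.4
            ]
            if len(keep) < 2 or tuple(keep) in chains:
                keep = None
                for _ in range(10):
                    drop = int(rng.integers(1, len(parent) - 1))
                    cand = [e for k, e in enumerate(parent) if k != drop]
                    if tuple(cand) not in chains:
                        keep = cand
                        break
                if keep is None:
                    break
            structures.append(keep)
            chains.add(tuple(keep))
        transcripts = []
        for ti, struct in enumerate(structures):
            tid = f"{gid}.T{ti}"
            exons = [Exon(cfg.chrom, s, e, strand) for s, e in struct]
            transcripts.append(Transcript(tid, gid, exons, biotype="protein_coding"))
            exon_records.extend(struct)
        genes.append(Gene(gid, transcripts, biotype="protein_coding"))
        pos = max(e for _, e in parent) + 500
        chrom_len = pos
    annotation = Annotation(genes)

    chrom_seq = rng.choice(_BASES, size=chrom_len + 10)
    seqs: dict[str, str] = {}
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    for tid, tx in annotation.transcripts.items():
        parts = [chrom_seq[e.start : e.end].tobytes() for e in tx.exons]
        s = b"".join(parts)
        if tx.strand == "-":
            s = s.translate(comp)[::-1]
        seqs[tid] = s.decode()
    return annotation, seqs


def generate_expression(
    annotation: Annotation,
    cfg: SimulationConfig,
    n_samples: int,
    seed: int | None = None,
) -> GroundTruth:
    """Draw true transcript CPM for ``n_samples`` replicates.

    Gene abundance is log-normal on the CPM scale, isoform usage is a
    per-gene Dirichlet draw shared across replicates, and replicate noise
    is multiplicative log-normal; each sample is renormalised to 10^6.
    """
    seed = cfg.seed if seed is None else seed
    rng = stage_rng(seed, "expression")
    tx_ids: list[str] = []
    base = []
    for gene in annotation.genes.values():
        g_expr = float(rng.lognormal(cfg.gene_expr_mu, cfg.gene_expr_sigma))
        k = len(gene.transcripts)
        if cfg.isoform_usage_concentration == np.inf or k == 1:
            usage = np.full(k, 1.0 / k)
        else:
            usage = rng.dirichlet(np.full(k, cfg.isoform_usage_concentration))
        subsets = subset_isoforms(gene)
        if subsets and cfg.subset_usage_multiplier != 1.0:
            scale = np.array(
                [cfg.subset_usage_multiplier if t.id in subsets else 1.0
                 for t in gene.transcripts]
            )
            usage = usage * scale
            usage = usage / usage.sum()
        for t, u in zip(gene.transcripts, usage):
            tx_ids.append(t.id)
            base.append(g_expr * u)
    base = np.asarray(base)
    cols = {}
    for s in range(n_samples):
        noise = (
            rng.lognormal(0.0, cfg.replicate_sigma, size=base.size)
            if cfg.replicate_sigma > 0
            else np.ones_like(base)
        )
        v = base * noise
        cols[f"sample{s}"] = v / v.sum() * 1e6
    cpm_df = pd.DataFrame(cols, index=pd.Index(tx_ids, name="transcript_id"))

    mean_cpm = cpm_df.mean(axis=1)
    majors = {}
    for gid, gene in annotation.genes.items():
        sub = mean_cpm[[t.id for t in gene.transcripts]].sort_index()
        majors[gid] = sub.idxmax()
    return GroundTruth(cpm_df, pd.Series(majors, name="major_isoform"))


def _sampling_weights(
    cpm: pd.Series, annotation: Annotation, profile: ProtocolProfile
) -> np.ndarray:
    w = cpm.to_numpy(dtype=float).copy()
    if profile.pcr_bias_epsilon:
        w = np.power(w, 1.0 + profile.pcr_bias_epsilon)
    if profile.length_midpoint is not None:
        lengths = np.array([annotation.transcripts[t].length for t in cpm.index])
        w = w / (1.0 + np.exp(-(lengths - profile.length_midpoint) / 150.0))
    return w


def simulate_long_reads(
    truth_cpm: pd.Series,
    annotation: Annotation,
    profile: ProtocolProfile | str,
    n_reads: int,
    seed: int,
    sample_index: int = 0,
) -> list[ReadAlignment]:
    """Simulate transcriptome-space long-read alignments for one sample.

    Transcripts are drawn multinomially with probability proportional to
    CPM times the protocol bias weight. With the profile's truncation
    probability the read's 5' end is uniform inside the transcript and the
    3' end stays at the transcript end (3'-anchored); otherwise the read is
    full length.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if isinstance(profile, str):
        profile = PROTOCOL_PROFILES[profile]
    rng = stage_rng(seed, "long_reads", sample_index)
    w = _sampling_weights(truth_cpm, annotation, profile)
    p = w / w.sum()
    counts = rng.multinomial(n_reads, p)
    reads: list[ReadAlignment] = []
    for tid, k in zip(truth_cpm.index, counts):
        if k == 0:
            continue
        length = annotation.transcripts[tid].length
        truncated = rng.random(k) < profile.truncation_prob
        starts = np.where(truncated, rng.integers(0, length, size=k), 0)
        for i, s in enumerate(starts):
            reads.append(
                ReadAlignment(
                    f"{tid}_lr{i}",
                    "transcriptome",
                    tid,
                    [(int(s), length)],
                    source=tid,
                )
            )
    return reads


def simulate_short_reads(
    truth_cpm: pd.Series,
    annotation: Annotation,
    n_reads: int,
    seed: int,
    fragment_length: int = 150,
    sample_index: int = 0,
) -> list[ReadAlignment]:
    """Simulate fixed-length short-read fragments in transcriptome space.

    Transcripts shorter than the fragment length are excluded. Transcripts
    are drawn with probability proportional to CPM x effective length
    (molecules x fragmentable positions); fragment starts are uniform over
    valid positions.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = stage_rng(seed, "short_reads", sample_index)
    lengths = np.array([annotation.transcripts[t].length for t in truth_cpm.index])
    eff = np.maximum(lengths - fragment_length + 1, 0)
    w = truth_cpm.to_numpy(dtype=float) * eff
    if w.sum() <= 0:
        raise ValueError("no transcript long enough for the fragment length")
    counts = rng.multinomial(n_reads, w / w.sum())
    reads: list[ReadAlignment] = []
    for tid, length, e, k in zip(truth_cpm.index, lengths, eff, counts):
        if k == 0:
            continue
        starts = rng.integers(0, e, size=k)
        for i, s in enumerate(starts):
            reads.append(
                ReadAlignment(
                    f"{tid}_sr{i}",
                    "transcriptome",
                    tid,
                    [(int(s), int(s) + fragment_length)],
                    source=tid,
                )
            )
    return reads


def generate_spikein(
    mix: dict[str, float],
    spike_fraction: float,
    n_total_reads: int,
    seed: int,
    transcript_lengths: dict[str, int],
) -> tuple[list[ReadAlignment], pd.DataFrame]:
    """Simulate full-length spike-in reads plus the concentration sheet.

    Expected spike reads = ``n_total_reads x spike_fraction``; per-transcript
    counts are multinomial on the relative concentrations (which must sum
    to 1). The sheet has columns transcript_id / gene_id / concentration /
    mix as written to CSV.
    """
    rel = np.array(list(mix.values()), dtype=float)
    if abs(rel.sum() - 1.0) > 1e-9:
        raise ValueError("spike-in relative concentrations must sum to 1")
    rng = stage_rng(seed, "spikein")
    n_spike = int(round(n_total_reads * spike_fraction))
    reads: list[ReadAlignment] = []
    if n_spike > 0:
        counts = rng.multinomial(n_spike, rel)
        for tid, k in zip(mix, counts):
            length = transcript_lengths[tid]
            for i in range(k):
                reads.append(
                    ReadAlignment(
                        f"{tid}_sp{i}", "transcriptome", tid, [(0, length)], source=tid
                    )
                )
    sheet = pd.DataFrame(
        {
            "transcript_id": list(mix),
            "gene_id": [f"spikein_{t}" for t in mix],
            "concentration": rel,
            "mix": "synthetic-mix",
        }
    )
    return reads, sheet
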