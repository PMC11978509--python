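"""In-silico fragmentation of long reads into fixed-length error-corrected
short reads, the 5'-anchored trimming series, and the fragmentation-impact
experiment.

Each retained long read (mapped length >= the fragment length L, default
150 bp) yields N = floor(mapped_length / L) fragments whose start positions
are uniform on [alignment_start, alignment_end - L]; fragment sequences are
reference substrings, i.e. error-corrected by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation
from .classify import ReadAlignment, build_read_classes
from .isoforms import category_agreement
from .quantify import cpm, em_quantify, log2_transform

__all__ = [
    "FragmentationParams",
    "Fragment",
    "fragment_read",
    "fragment_reads",
    "fragments_to_reads",
    "trim_reads",
    "fragmentation_experiment",
]


@dataclass(frozen=True)
class FragmentationParams:
    L: int = 150
    min_mapped: int = 150
    n_rule: str = "floor"  # or "uniform": N ~ U{1, floor(mapped/L)}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("fragment length must be >= 1")
        if self.min_mapped < self.L:
            raise ValueError("min_mapped must be >= fragment length")
        if self.n_rule not in ("floor", "uniform"):
            raise ValueError(f"unknown n_rule {self.n_rule!r}")


@dataclass(frozen=True)
class Fragment:
    source_read_id: str
    transcript_id: str
    start: int  # transcript-space
    end: int


def fragment_read(
    read: ReadAlignment, params: FragmentationParams, rng: np.random.Generator
) -> list[Fragment]:
    """Fragment one transcriptome-space read; [] if below min_mapped.

    N = floor(mapped_length / L) fragments (or uniform on [1, N] under the
    ``uniform`` rule); each start is drawn from the discrete uniform on
    [aln_start, aln_end - L] inclusive.
    """
    if read.space != "transcriptome":
        raise ValueError("fragmentation operates on transcriptome-space alignments")
    mapped = read.mapped_length
    if mapped < params.min_mapped:
        return []
    n_max = mapped // params.L
    n = n_max if params.n_rule == "floor" else int(rng.integers(1, n_max + 1))
    starts = rng.integers(read.start, read.end - params.L + 1, size=n)
    return [
        Fragment(read.read_id, read.target, int(s), int(s) + params.L) for s in starts
    ]


def fragment_reads(
    reads: list[ReadAlignment], params: FragmentationParams
) -> tuple[list[Fragment], int]:
    """Fragment a read population; returns (fragments, n_skipped)."""
    rng = np.random.default_rng([97, params.seed])
    fragments: list[Fragment] = []
    skipped = 0
    for read in reads:
        out = fragment_read(read, params, rng)
        if not out:
            skipped += 1
        fragments.extend(out)
    return fragments, skipped


def fragments_to_reads(
    fragments: list[Fragment],
    sequences: dict[str, str] | None = None,
    fastq_path=None,
) -> list[ReadAlignment]:
    """Turn fragments into short-read alignment records (and optional FASTQ).

    Sequences, when provided, are reference substrings in transcript
    orientation (never reverse-complemented); quality is uniform.
    """
    reads = []
    fastq = open(fastq_path, "w") if fastq_path else None
    try:
        for i, f in enumerate(fragments):
            rid = f"{f.source_read_id}_f{i}"
            if sequences is not None:
                seq = sequences[f.transcript_id]
                if f.end > len(seq):
                    raise ValueError(
                        f"fragment {rid} exceeds transcript {f.transcript_id} end"
                    )
                if fastq is not None:
                    sub = seq[f.start : f.end]
                    fastq.write(f"@{rid}\n{sub}\n+\n{'I' * len(sub)}\n")
            reads.append(
                ReadAlignment(
                    rid,
                    "transcriptome",
                    f.transcript_id,
                    [(f.start, f.end)],
                    source=f.source_read_id,
                )
            )
    finally:
        if fastq is not None:
            fastq.close()
    return reads


def trim_reads(sequences: list[str], target_length: int) -> tuple[list[str], int]:
    """5'-anchored trimming: keep the first ``target_length`` bases.

    Reads already shorter than the target pass through unchanged; the count
    of such reads is returned alongside.
    """
    passed_through = sum(1 for s in sequences if len(s) < target_length)
    return [s[:target_length] for s in sequences], passed_through


def _quantify_sample(
    reads, annotation, fragment_mode: bool, effective_lengths=None
):
    classes = build_read_classes(reads, annotation)
    counts = em_quantify(
        classes,
        transcripts=sorted(annotation.transcripts),
        effective_lengths=effective_lengths if fragment_mode else None,
    )
    return counts


def fragmentation_experiment(
    long_reads: list[ReadAlignment],
    annotation: Annotation,
    tx_table: pd.DataFrame,
    params: FragmentationParams,
    short_read_cpm: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> dict:
    """Quantify a long-read sample before and after in-silico fragmentation
    and measure per-category agreement.

    Returns a dict with the original and fragmented CPM estimates, the
    per-category Spearman/MAE between their log2 values, and, when an
    independent short-read CPM vector is supplied, the overall Spearman of
    each against it.
    """
    from scipy import stats

    eff = pd.Series(
        {
            t.id: max(t.length - params.L + 1, 1)
            for t in annotation.transcripts.values()
        }
    )
    orig_counts = _quantify_sample(long_reads, annotation, fragment_mode=False)
    fragments, n_skipped = fragment_reads(long_reads, params)
    frag_alns = fragments_to_reads(fragments)
    frag_counts = _quantify_sample(
        frag_alns, annotation, fragment_mode=True, effective_lengths=eff
    )

    orig_cpm = cpm(orig_counts)
    frag_cpm = cpm(frag_counts)
    log_orig = log2_transform(orig_cpm, pseudocount)
    log_frag = log2_transform(frag_cpm, pseudocount)

    result = {
        "original_cpm": orig_cpm,
        "fragmented_cpm": frag_cpm,
        "n_fragments": len(fragments),
        "n_skipped_reads": n_skipped,
        "spearman_by_category": category_agreement(
            log_orig, log_frag, tx_table, metric="spearman"
        ),
        "mae_by_category": category_agreement(log_orig, log_frag, tx_table, metric="mae"),
    }
    if short_read_cpm is not None:
        log_sr = log2_transform(short_read_cpm.reindex(orig_cpm.index).fillna(0.0), pseudocount)
        result["spearman_sr_vs_original"] = float(
            stats.spearmanr(log_orig.to_numpy(), log_sr.to_numpy()).statistic
        )
        result["spearman_sr_vs_fragmented"] = float(
            stats.spearmanr(log_frag.to_numpy(), log_sr.to_numpy()).statistic
        )
    return result
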