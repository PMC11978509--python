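"""Coverage-bias profiles, transcript-diversity curves and the
length-adjusted gene-coverage ratio with its two-proportion z-test.

Coverage profiles divide each transcript into 100 equal bins, average the
per-base depth within each bin and normalise by the maximum bin, so every
expressed transcript's profile peaks at 1. Deletions inside read alignments
are treated as covered (they are merged into blocks upstream). Diversity
curves rank genes (by expression, descending, or by gene length,
ascending) and accumulate read fractions; ties produce a linear segment,
the interpolation across tied ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, gene_length

__all__ = [
    "CoverageProfile",
    "transcript_coverage",
    "binned_profile",
    "aggregate_profiles",
    "diversity_curve",
    "median_curve",
    "top_k_fraction",
    "gene_coverage_ratio",
    "ratio_ztest",
]

N_BINS = 100


@dataclass
class CoverageProfile:
    transcript_id: str
    bins: np.ndarray  # 100 values in [0, 1], max 1 when covered
    n_reads: int


def transcript_coverage(alignments, transcript_length: int) -> np.ndarray:
    """Per-base depth over a transcript from transcriptome-space alignments.

    Blocks already include deletion-spanned bases, so depth counts them as
    covered.
    """
    depth = np.zeros(transcript_length, dtype=np.int64)
    for aln in alignments:
        for s, e in aln.blocks:
            depth[max(s, 0) : min(e, transcript_length)] += 1
    return depth


def binned_profile(
    depth: np.ndarray, transcript_id: str = "", n_reads: int | None = None
) -> CoverageProfile | None:
    """Mean depth in 100 equal bins, normalised by the maximum bin.

    Bin i covers positions [floor(i*L/100), floor((i+1)*L/100)). Transcripts
    shorter than 100 bases or with zero coverage return None (excluded and
    counted by callers).
    """
    length = len(depth)
    if length < N_BINS or depth.max() == 0:
        return None
    edges = (np.arange(N_BINS + 1) * length) // N_BINS
    sums = np.add.reduceat(depth, edges[:-1])
    means = sums / np.diff(edges)
    profile = means / means.max()
    return CoverageProfile(transcript_id, profile, int(n_reads or 0))


def aggregate_profiles(profiles: list[np.ndarray]) -> np.ndarray:
    """Per-bin arithmetic mean of normalised profiles (one grouping level)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    return np.mean(np.vstack(profiles), axis=0)


def diversity_curve(
    counts: pd.Series,
    ranking: str = "expression_desc",
    lengths: pd.Series | None = None,
) -> np.ndarray:
    """Cumulative read fraction per gene rank.

    ``expression_desc`` ranks genes from highest to lowest count (tied
    counts yield a linear segment across the tied rank span);
    ``length_asc`` ranks by gene length, shortest first.
    """
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("all-zero gene counts")
    if ranking == "expression_desc":
        ordered = np.sort(counts.to_numpy(dtype=float))[::-1]
    elif ranking == "length_asc":
        if lengths is None:
            raise ValueError("length ranking requires gene lengths")
        ordered = counts.reindex(lengths.sort_values(kind="stable").index).to_numpy(
            dtype=float
        )
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    return np.cumsum(ordered) / total


def median_curve(curves: list[np.ndarray]) -> np.ndarray:
    """Per-protocol summary: median cumulative fraction across samples."""
    n = min(len(c) for c in curves)
    return np.median(np.vstack([c[:n] for c in curves]), axis=0)


def top_k_fraction(curve: np.ndarray, k: int = 1000) -> float:
    """Cumulative read fraction attributed to the top-k ranked genes."""
    return float(curve[min(k, len(curve)) - 1])


def gene_coverage_ratio(
    classes, annotation: Annotation, gene_id: str, width_mode: str = "span"
) -> float:
    """Length-adjusted over raw read count for one gene.

    ratio = sum_c(count_c * width_c / L_max) / sum_c(count_c), with L_max
    the gene length (maximum isoform length); 1 means every read class
    spans the longest isoform's width. ``width_mode`` selects the genomic
    span of the class (default) or its summed block widths
    (``"blocks"``); either is capped at L_max. Intended for genes above
    the 30-CPM expression gate in all compared protocols.
    """
    if width_mode not in ("span", "blocks"):
        raise ValueError(f"unknown width_mode {width_mode!r}")
    l_max = gene_length(annotation.genes[gene_id])
    num = 0.0
    den = 0.0
    for c in classes:
        width = c.width if width_mode == "span" else c.exonic_width
        num += c.count * min(width / l_max, 1.0)
        den += c.count
    if den == 0:
        return float("nan")
    return num / den


def ratio_ztest(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided z-test on two proportions without assuming equal variance.

    z = (r1 - r2) / sqrt(r1(1-r1)/n1 + r2(1-r2)/n2); the p-value comes from
    the standard normal. Degenerate variance on both sides returns NaN.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    var = r1 * (1 - r1) / n1 + r2 * (1 - r2) / n2
    if var == 0:
        if r1 == r2:
            return 0.0, 1.0
        return float("nan"), float("nan")
    z = (r1 - r2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
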