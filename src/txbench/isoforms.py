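"""Major-isoform identification, four-way categorisation and per-category
agreement metrics between sequencing technologies.

For each gene and condition (cell line) the *major isoform* is the
transcript with the highest mean expression estimate over a technology's
replicates. Comparing the long-read and short-read majors partitions all
transcripts of the included genes into: ``major_shared`` (the common major
when both technologies agree), ``major_LR_specific`` and
``major_SR_specific`` (when they disagree), and ``minor`` (never a major).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MAJOR_SHARED",
    "MAJOR_LR",
    "MAJOR_SR",
    "MINOR",
    "major_isoform",
    "majors_from_matrix",
    "categorize",
    "concordance",
    "category_agreement",
    "expressed_fraction",
]

MAJOR_SHARED = "major_shared"
MAJOR_LR = "major_LR_specific"
MAJOR_SR = "major_SR_specific"
MINOR = "minor"


def major_isoform(transcript_ids, mean_expression: pd.Series) -> str | None:
    """Argmax transcript of a gene; lexicographic tie-break; None if the
    gene has zero expression on every transcript."""
    sub = mean_expression.reindex(sorted(transcript_ids)).fillna(0.0)
    if float(sub.max()) <= 0:
        return None
    return sub.idxmax()


def majors_from_matrix(matrix: pd.DataFrame, annotation) -> pd.Series:
    """Per-gene major isoform from the mean over a technology's replicate
    columns; all-zero genes are omitted."""
    mean = matrix.mean(axis=1)
    out = {}
    for gid, gene in annotation.genes.items():
        tids = [t.id for t in gene.transcripts if t.id in mean.index]
        if not tids:
            continue
        m = major_isoform(tids, mean)
        if m is not None:
            out[gid] = m
    return pd.Series(out, name="major_isoform")


def categorize(
    lr_major: pd.Series, sr_major: pd.Series, annotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-transcript category table.

    Only genes with a major isoform in both technologies are included;
    excluded genes are counted in the per-gene table. Returns
    ``(transcript_table, gene_table)``: the first maps transcript_id ->
    (gene_id, category), the second gene_id -> (lr_major, sr_major).
    """
    genes_lr = set(lr_major.index)
    genes_sr = set(sr_major.index)
    union = genes_lr | genes_sr
    unknown = union - set(annotation.genes)
    if unknown:
        raise ValueError(f"majors reference genes absent from annotation: {sorted(unknown)[:5]}")
    shared_genes = sorted(genes_lr & genes_sr)

    gene_rows = []
    tx_rows = []
    for gid in shared_genes:
        lr, sr = lr_major[gid], sr_major[gid]
        gene_rows.append((gid, lr, sr, lr == sr))
        for t in annotation.genes[gid].transcripts:
            if lr == sr:
                cat = MAJOR_SHARED if t.id == lr else MINOR
            elif t.id == lr:
                cat = MAJOR_LR
            elif t.id == sr:
                cat = MAJOR_SR
            else:
                cat = MINOR
            tx_rows.append((t.id, gid, cat))
    tx_table = pd.DataFrame(
        tx_rows, columns=["transcript_id", "gene_id", "category"]
    ).set_index("transcript_id")
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "lr_major", "sr_major", "agree"]
    ).set_index("gene_id")
    gene_table.attrs["n_excluded"] = len(union) - len(shared_genes)
    return tx_table, gene_table


def concordance(gene_table: pd.DataFrame) -> tuple[int, int]:
    """(n_agree, n_disagree) over genes with majors in both technologies."""
    n_agree = int(gene_table["agree"].sum())
    return n_agree, len(gene_table) - n_agree


def category_agreement(
    expr_a: pd.Series,
    expr_b: pd.Series,
    tx_table: pd.DataFrame,
    metric: str = "spearman",
) -> pd.Series:
    """Per-category agreement between two log2 expression vectors.

    ``metric`` is ``spearman`` or ``mae``; categories with fewer than
    3 transcripts yield NaN.
    """
    if metric not in ("spearman", "mae"):
        raise ValueError(f"unknown metric {metric!r}")
    shared = tx_table.index.intersection(expr_a.index).intersection(expr_b.index)
    cats = tx_table.loc[shared, "category"]
    out = {}
    for cat in (MAJOR_SHARED, MAJOR_LR, MAJOR_SR, MINOR):
        ids = cats.index[cats == cat]
        if len(ids) < 3:
            out[cat] = np.nan
            continue
        a = expr_a[ids].to_numpy(dtype=float)
        b = expr_b[ids].to_numpy(dtype=float)
        if metric == "spearman":
            rho = stats.spearmanr(a, b).statistic
            out[cat] = float(rho)
        else:
            out[cat] = float(np.mean(np.abs(a - b)))
    return pd.Series(out, name=metric)


def expressed_fraction(
    cpm: pd.Series, tx_table: pd.DataFrame, threshold: float = 1.0
) -> pd.Series:
    """Fraction of each category's transcripts expressed at >= threshold CPM."""
    shared = tx_table.index.intersection(cpm.index)
    cats = tx_table.loc[shared, "category"]
    out = {}
    for cat in (MAJOR_SHARED, MAJOR_LR, MAJOR_SR, MINOR):
        ids = cats.index[cats == cat]
        out[cat] = float((cpm[ids] >= threshold).mean()) if len(ids) else np.nan
    return pd.Series(out, name="expressed_fraction")
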