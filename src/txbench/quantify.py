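"""Transcript quantification: uniqueness counting plus EM over ambiguous
read classes, CPM/TPM normalisation and gene-level aggregation.

The EM operates on the read-class compatibility structure: the E-step
splits each class's read count across its compatible transcripts in
proportion to the current abundance estimate (optionally divided by the
effective length, for fragment-mode data), and the M-step renormalises.
Estimated counts always sum to the total assigned class count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "em_quantify",
    "em_log_likelihood",
    "cpm",
    "tpm",
    "gene_expression",
    "log2_transform",
]


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundances with per-sample metadata.

    ``data`` is indexed by transcript id with one column per sample id;
    ``meta`` is indexed by sample id with columns cell_line / protocol /
    replicate.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\t" + "\t".join(self.data.columns) + "\n")
            meta_line = [
                "{cell_line}/{protocol}/{replicate}".format(**self.meta.loc[s])
                for s in self.data.columns
            ]
            fh.write("#meta\t" + "\t".join(meta_line) + "\n")
            self.data.to_csv(fh, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            meta_line = fh.readline().rstrip("\n").split("\t")
            data = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        samples = header[1:]
        data.columns = samples
        data.index.name = "feature_id"
        meta = pd.DataFrame(
            [dict(zip(("cell_line", "protocol", "replicate"), m.split("/")))
             for m in meta_line[1:]],
            index=samples,
        )
        return cls(data, meta)


def _prepare(classes, transcripts):
    """Build the sparse class x transcript membership matrix."""
    items = []
    for c in classes:
        if isinstance(c, (tuple, list)):
            count, compat = c[0], c[1]
        else:
            count, compat = c.count, c.compatible
        if not compat:
            raise ValueError("read class with empty compatibility passed to EM")
        items.append((float(count), sorted(compat)))
    if transcripts is None:
        transcripts = sorted({t for _, compat in items for t in compat})
    tx_index = {t: i for i, t in enumerate(transcripts)}
    rows, cols = [], []
    counts = np.zeros(len(items))
    for r, (count, compat) in enumerate(items):
        counts[r] = count
        for t in compat:
            rows.append(r)
            cols.append(tx_index[t])
    M = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(items), len(transcripts))
    )
    return M, counts, list(transcripts)


def em_quantify(
    classes,
    transcripts=None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    effective_lengths: pd.Series | dict | None = None,
) -> pd.Series:
    """Estimate per-transcript read counts by EM over read classes.

    ``classes`` is an iterable of objects with ``count`` and ``compatible``
    attributes (or ``(count, compatible)`` tuples); unassigned classes must
    be excluded by the caller. ``effective_lengths`` switches on
    fragment-mode length weighting. Initialisation is uniform and the
    procedure is fully deterministic.
    """
    classes = list(classes)
    if not classes:
        return pd.Series(dtype=float, name="est_counts")
    M, counts, tx_ids = _prepare(classes, transcripts)
    n_tx = len(tx_ids)
    total = counts.sum()

    if effective_lengths is not None:
        inv_len = np.array(
            [1.0 / max(float(effective_lengths[t]), 1.0) for t in tx_ids]
        )
    else:
        inv_len = np.ones(n_tx)

    a = np.full(n_tx, total / n_tx)
    converged = False
    for _ in range(max_iter):
        w = a * inv_len
        denom = M @ w
        # classes always have >=1 compatible transcript; denom>0 unless a
        # transcript hit zero abundance — guard against 0/0
        denom = np.where(denom > 0, denom, 1.0)
        a_new = (M.T @ (counts / denom)) * w
        s = a_new.sum()
        if s > 0:
            a_new *= total / s
        if np.abs(a_new - a).sum() <= tol * max(total, 1.0):
            a = a_new
            converged = True
            break
        a = a_new
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)
    return pd.Series(a, index=pd.Index(tx_ids, name="transcript_id"), name="est_counts")


def em_log_likelihood(classes, abundances: pd.Series, effective_lengths=None) -> float:
    """Multinomial log-likelihood of read classes under abundance estimates."""
    a = abundances.astype(float)
    if effective_lengths is not None:
        w = a / np.array([max(float(effective_lengths[t]), 1.0) for t in a.index])
    else:
        w = a
    w = w / w.sum()
    ll = 0.0
    for c in classes:
        if isinstance(c, (tuple, list)):
            count, compat = c[0], c[1]
        else:
            count, compat = c.count, c.compatible
        p = float(w[list(compat)].sum())
        if p <= 0:
            return float("-inf")
        ll += count * np.log(p)
    return ll


def cpm(counts: pd.Series | pd.DataFrame):
    """Counts per million: count / per-sample total x 10^6."""
    total = counts.sum(axis=0) if isinstance(counts, pd.DataFrame) else counts.sum()
    if np.any(np.asarray(total) <= 0):
        raise ValueError("cannot compute CPM with zero total counts")
    return counts / total * 1e6


def tpm(counts: pd.Series | pd.DataFrame, effective_lengths: pd.Series):
    """Transcripts per million: length-normalised rate rescaled to 10^6."""
    lens = effective_lengths.reindex(counts.index)
    if lens.isna().any():
        raise ValueError("missing effective length for some transcripts")
    rate = counts.div(lens.clip(lower=1.0), axis=0)
    total = rate.sum(axis=0) if isinstance(rate, pd.DataFrame) else rate.sum()
    if np.any(np.asarray(total) <= 0):
        raise ValueError("cannot compute TPM with zero total rate")
    return rate / total * 1e6


def gene_expression(matrix: pd.DataFrame, annotation) -> pd.DataFrame:
    """Aggregate a transcript x sample matrix to genes by summation."""
    gene_ids = []
    for tid in matrix.index:
        tx = annotation.transcripts.get(tid)
        if tx is None:
            raise KeyError(f"transcript {tid} not in annotation")
        gene_ids.append(tx.gene_id)
    out = matrix.groupby(pd.Index(gene_ids, name="gene_id")).sum()
    return out


def log2_transform(matrix, pseudocount: float = 1.0):
    """log2(value + pseudocount); values must be non-negative."""
    arr = np.asarray(matrix, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative values in expression matrix")
    return np.log2(matrix + pseudocount)
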