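#!/usr/bin/env python
"""Long-read vs short-read major isoforms: concordance, four-way
categorisation and the fraction of each category expressed at >= 1 CPM.

Uses the unbiased long-read sample (IsoSeq-like, no truncation is closest)
against the fragment sample. Writes results/major_isoforms.tsv and
results/category_summary.tsv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from txbench.annotation import read_gtf
from txbench.io import read_alignment_tsv
from txbench.isoforms import categorize, concordance, expressed_fraction, majors_from_matrix
from txbench.pipeline import quantify_sample
from txbench.quantify import cpm

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("scratch/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

annotation = read_gtf(args.datadir / "annotation.gtf")
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    lr_cpm = cpm(
        quantify_sample(
            read_alignment_tsv(args.datadir / "reads_IsoSeq-like.tsv"), annotation
        )
    )
    sr_cpm = cpm(
        quantify_sample(
            read_alignment_tsv(args.datadir / "reads_short.tsv"),
            annotation,
            fragment_mode=True,
        )
    )

lr_major = majors_from_matrix(pd.DataFrame({"lr": lr_cpm}), annotation)
sr_major = majors_from_matrix(pd.DataFrame({"sr": sr_cpm}), annotation)
tx_table, gene_table = categorize(lr_major, sr_major, annotation)
n_agree, n_disagree = concordance(gene_table)

args.outdir.mkdir(parents=True, exist_ok=True)
gene_table.to_csv(args.outdir / "major_isoforms.tsv", sep="\t")

summary = pd.DataFrame(
    {
        "n_transcripts": tx_table.groupby("category").size(),
        "lr_expressed_fraction": expressed_fraction(lr_cpm, tx_table),
        "sr_expressed_fraction": expressed_fraction(sr_cpm, tx_table),
    }
)
summary.to_csv(args.outdir / "category_summary.tsv", sep="\t", float_format="%.4f")

print(f"majors agree for {n_agree} genes, disagree for {n_disagree} "
      f"({gene_table.attrs['n_excluded']} genes excluded)")
print(summary.round(3).to_string())
print(f"\nwrote {args.outdir / 'major_isoforms.tsv'} and {args.outdir / 'category_summary.tsv'}")
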