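#!/usr/bin/env python
"""Classify each protocol's reads against the annotation and tabulate
full-splice-match fractions, junction coverage and assignment ambiguity.

Expects the dataset from 01_simulate_dataset.py; writes
results/read_classification.tsv. The expected picture: full-length
protocols (IsoSeq-like, PCR-cDNA-like) have the highest FSM fraction and
the most uniquely assigned reads; 150-bp fragments cover almost no
junctions and are assigned to several transcripts.
"""

import argparse
from pathlib import Path

import pandas as pd

from txbench.annotation import read_gtf
from txbench.classify import build_read_classes, junctions_per_read, unique_assignment_stats
from txbench.io import read_alignment_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("scratch/data"))
parser.add_argument("--out", type=Path, default=Path("results/read_classification.tsv"))
args = parser.parse_args()

annotation = read_gtf(args.datadir / "annotation.gtf")
rows = []
for path in sorted(args.datadir.glob("reads_*.tsv")):
    sample = path.stem.removeprefix("reads_")
    reads = read_alignment_tsv(path)
    classes = build_read_classes(reads, annotation)
    n_assigned = sum(c.count for c in classes)
    n_fsm = sum(c.count for c in classes if c.label == "full_splice_match")
    _, unique_fraction = unique_assignment_stats(classes)
    mean_junc = sum(junctions_per_read(r, annotation) for r in reads) / len(reads)
    rows.append(
        {
            "sample": sample,
            "n_reads": len(reads),
            "assigned_fraction": n_assigned / len(reads),
            "fsm_fraction": n_fsm / n_assigned,
            "unique_fraction": unique_fraction,
            "mean_junctions_per_read": mean_junc,
        }
    )

table = pd.DataFrame(rows).set_index("sample")
args.out.parent.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out, sep="\t", float_format="%.4f")
print(table.round(3).to_string())
print(f"\nwrote {args.out}")
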