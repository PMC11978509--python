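#!/usr/bin/env python
"""Generate the synthetic study dataset: annotation with subset-isoform
genes, transcript sequences, ground-truth expression, and per-protocol
read populations.

Writes GTF/FASTA/ground-truth tables under results/data/ and prints a
short census of what was generated.
"""

import argparse
from pathlib import Path

from txbench.annotation import subset_isoforms, write_gtf
from txbench.io import write_alignment_tsv
from txbench.simulate import (
    PROTOCOL_PROFILES,
    SimulationConfig,
    generate_annotation,
    generate_expression,
    simulate_long_reads,
    simulate_short_reads,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("scratch/data"))
args = parser.parse_args()

cfg = SimulationConfig(n_genes=200, n_reads=30_000, seed=args.seed)
args.outdir.mkdir(parents=True, exist_ok=True)

annotation, seqs = generate_annotation(cfg)
truth = generate_expression(annotation, cfg, n_samples=4)

write_gtf(annotation, args.outdir / "annotation.gtf")
with open(args.outdir / "transcripts.fa", "w") as fh:
    for tid, seq in seqs.items():
        fh.write(f">{tid}\n{seq}\n")
truth.cpm.to_csv(args.outdir / "truth_cpm.tsv", sep="\t")
truth.major_isoform.to_csv(args.outdir / "truth_major_isoforms.tsv", sep="\t")

n_subset = sum(bool(subset_isoforms(g)) for g in annotation.genes.values())
print(
    f"generated {len(annotation.genes)} genes / {len(annotation.transcripts)} "
    f"transcripts ({n_subset} genes carry a subset isoform), seed={args.seed}"
)

for name in PROTOCOL_PROFILES:
    reads = simulate_long_reads(
        truth.cpm.iloc[:, 0], annotation, name, cfg.n_reads, args.seed
    )
    write_alignment_tsv(reads, args.outdir / f"reads_{name}.tsv")
    mean_len = sum(r.mapped_length for r in reads) / len(reads)
    print(f"  {name}: {len(reads)} reads, mean aligned length {mean_len:.0f} bp")

sr = simulate_short_reads(truth.cpm.iloc[:, 1], annotation, cfg.n_reads * 3, args.seed)
write_alignment_tsv(sr, args.outdir / "reads_short.tsv")
print(f"  short-read: {len(sr)} 150-bp fragments")
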