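#!/usr/bin/env python
"""The fragmentation-impact study: fragment unbiased long reads into
150-bp reads in silico and compare per-category agreement, over 20 seeds.

Writes results/fragmentation_study.tsv. The expected picture: agreement
between original and fragmented estimates is highest for shared major
isoforms, lower for long-read-specific majors and lowest for
short-read-specific majors, and fragmentation moves long-read estimates
toward the independent short-read estimates.
"""

import argparse
from pathlib import Path

from txbench.experiments import fragmentation_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-seeds", type=int, default=20)
parser.add_argument("--out", type=Path, default=Path("results/fragmentation_study.tsv"))
args = parser.parse_args()

table = fragmentation_study(range(1, args.n_seeds + 1), base_seed=args.seed)
args.out.parent.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out, sep="\t", float_format="%.4f")

print(table.round(3).to_string())
print(
    f"\nordering shared >= LR-specific >= SR-specific holds in "
    f"{table['ordering_holds'].mean():.0%} of seeds; "
    f"Spearman vs short reads: {table['spearman_sr_vs_original'].mean():.3f} "
    f"before fragmentation, {table['spearman_sr_vs_fragmented'].mean():.3f} after"
)
print(f"wrote {args.out}")
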