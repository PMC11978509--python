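#!/usr/bin/env python
"""Quantify every simulated sample with the EM and measure how well the
estimates recover the ground truth, overall and per protocol.

Writes results/quantification_recovery.tsv. The unbiased/IsoSeq-like
protocols should recover truth almost perfectly; PCR-cDNA-like is
concentration-biased, and fragment data lose rank accuracy for minor
isoforms.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd
from scipy import stats

from txbench.annotation import read_gtf
from txbench.experiments import parameter_recovery
from txbench.io import read_alignment_tsv
from txbench.pipeline import quantify_sample
from txbench.quantify import cpm, log2_transform

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--datadir", type=Path, default=Path("scratch/data"))
parser.add_argument("--out", type=Path, default=Path("results/quantification_recovery.tsv"))
args = parser.parse_args()

annotation = read_gtf(args.datadir / "annotation.gtf")
truth = pd.read_csv(args.datadir / "truth_cpm.tsv", sep="\t", index_col=0)

rows = []
for path in sorted(args.datadir.glob("reads_*.tsv")):
    sample = path.stem.removeprefix("reads_")
    reads = read_alignment_tsv(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counts = quantify_sample(reads, annotation, fragment_mode=sample == "short")
    est = cpm(counts)
    true_col = truth.iloc[:, 1 if sample == "short" else 0].reindex(est.index)
    rho = stats.spearmanr(log2_transform(est), log2_transform(true_col)).statistic
    rows.append({"sample": sample, "n_reads": len(reads),
                 "spearman_log2_true_vs_est": float(rho)})

table = pd.DataFrame(rows).set_index("sample")
args.out.parent.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out, sep="\t", float_format="%.4f")
print(table.round(3).to_string())

rec = parameter_recovery(seed=args.seed + 2024)
print(
    f"\ndedicated recovery run (200 genes, 10^5 unbiased reads): "
    f"Spearman {rec['spearman_true_vs_estimated']:.3f}, "
    f"major-isoform recovery {rec['major_recovery_rate']:.1%} "
    f"on {rec['n_gapped_genes']} gapped genes"
)
print(f"wrote {args.out}")
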