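"""Spike-in quantification evaluation: expected CPM from concentration
sheets and the six-metric agreement suite on the log2 scale."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import log2_transform

__all__ = [
    "SpikeInMix",
    "MetricReport",
    "read_mix_sheet",
    "expected_cpm",
    "quant_metrics",
    "protocol_comparison",
]


@dataclass
class SpikeInMix:
    """One spike-in mix: per-transcript relative concentration fractions."""

    name: str
    fractions: pd.Series  # transcript_id -> relative concentration, sums to 1
    gene_of: pd.Series | None = None  # transcript_id -> spike-in gene grouping

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix {self.name}: relative fractions sum to {total}, not 1")


@dataclass
class MetricReport:
    spearman: float
    mae: float
    mrad: float
    mrd: float
    rmse: float
    r_squared: float

    def as_dict(self) -> dict[str, float]:
        return self.__dict__.copy()


def read_mix_sheet(path) -> dict[str, SpikeInMix]:
    """Read a concentration CSV (transcript_id, gene_id, concentration, mix)
    into mixes with normalised relative fractions."""
    df = pd.read_csv(path)
    mixes = {}
    for name, sub in df.groupby("mix"):
        conc = sub.set_index("transcript_id")["concentration"].astype(float)
        mixes[name] = SpikeInMix(
            str(name),
            conc / conc.sum(),
            sub.set_index("transcript_id")["gene_id"],
        )
    return mixes


def expected_cpm(total_reads: int, spike_fraction: float, mix: SpikeInMix) -> pd.Series:
    """Per-transcript expected CPM for a spike-in mix.

    Expected reads per transcript = total x fraction x relative
    concentration; on the CPM scale the total cancels, giving
    fraction x rel x 10^6.
    """
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    if not 0 < spike_fraction <= 1:
        raise ValueError("spike fraction must be in (0, 1]")
    return (mix.fractions * spike_fraction * 1e6).rename("expected_cpm")


def quant_metrics(
    estimated: pd.Series, expected: pd.Series, rel_denominator: str = "expected"
) -> MetricReport:
    """Agreement metrics between estimated and expected log2 expression.

    With x = expected and e = estimated: mae = mean|e-x|, mrd =
    mean((e-x)/x), mrad = mean(|e-x|/x), rmse = sqrt(mean((e-x)^2)), r^2 =
    squared Pearson. ``rel_denominator='mean'`` switches the relative
    metrics to the symmetric (e+x)/2 denominator. Relative metrics are NaN
    when any denominator is 0.
    """
    idx = estimated.index.intersection(expected.index)
    if len(idx) < 3:
        raise ValueError("need at least 3 paired values")
    e = estimated[idx].to_numpy(dtype=float)
    x = expected[idx].to_numpy(dtype=float)
    diff = e - x
    denom = x if rel_denominator == "expected" else (e + x) / 2.0
    if np.any(denom == 0):
        mrd = mrad = float("nan")
    else:
        mrd = float(np.mean(diff / denom))
        mrad = float(np.mean(np.abs(diff) / np.abs(denom)))
    return MetricReport(
        spearman=float(stats.spearmanr(e, x).statistic),
        mae=float(np.mean(np.abs(diff))),
        mrad=mrad,
        mrd=mrd,
        rmse=float(np.sqrt(np.mean(diff**2))),
        r_squared=float(stats.pearsonr(e, x).statistic ** 2),
    )


def protocol_comparison(
    estimates: dict[str, pd.Series],
    mixes: dict[str, SpikeInMix],
    spike_fraction: float,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Metric table per (protocol, mix, level).

    ``estimates`` maps protocol name to pooled spike-in CPM estimates (the
    spike-in reads of one protocol and mix combined into one sample).
    Gene-level evaluation sums transcript CPM by the mix's gene grouping.
    """
    rows = []
    for proto, est in estimates.items():
        for mix_name, mix in mixes.items():
            exp_tx = expected_cpm(1_000_000, spike_fraction, mix)
            est_tx = est.reindex(mix.fractions.index).fillna(0.0)
            for level in ("transcript", "gene"):
                if level == "gene" and mix.gene_of is not None:
                    e = est_tx.groupby(mix.gene_of).sum()
                    x = exp_tx.groupby(mix.gene_of).sum()
                else:
                    e, x = est_tx, exp_tx
                report = quant_metrics(
                    log2_transform(e, pseudocount), log2_transform(x, pseudocount)
                )
                rows.append(
                    {"protocol": proto, "mix": mix_name, "level": level}
                    | report.as_dict()
                )
    return pd.DataFrame(rows)
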