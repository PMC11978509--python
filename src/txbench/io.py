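"""Tabular I/O helpers: alignment TSVs and provenance headers."""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from . import __version__
from .classify import ReadAlignment

__all__ = [
    "write_alignment_tsv",
    "read_alignment_tsv",
    "provenance_header",
]


def write_alignment_tsv(reads: list[ReadAlignment], path) -> None:
    """Write transcriptome-space alignments as TSV
    (read_id, transcript_id, start, end; 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\tstart\tend\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.target}\t{r.start}\t{r.end}\n")


def read_alignment_tsv(path) -> list[ReadAlignment]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ReadAlignment(row.read_id, "transcriptome", row.transcript_id,
                      [(int(row.start), int(row.end))])
        for row in df.itertuples(index=False)
    ]


def provenance_header(seed: int, config: dict | None = None) -> str:
    """Comment header recording version, seed and a config hash."""
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# txbench {__version__} seed={seed} config={digest}\n"
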