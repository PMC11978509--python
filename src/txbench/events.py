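"""Pairwise structural comparison of isoforms and the simulated background
null for event enrichment.

Events are decided from exon/junction coordinates alone, strand-aware
("first" means the 5' terminal exon in transcript orientation):

- ``internal_first_exon`` / ``internal_last_exon``: the query's terminal
  exon shares its inner junction boundary with a non-terminal exon of the
  subject (the query looks like a shorter version of the subject that
  starts or ends at one of the subject's internal exons).
- ``alternative_first_exon`` / ``alternative_last_exon``: the terminal
  exons do not overlap and the query terminal exon does not match an
  internal subject exon.
- ``exon_skipping``: a subject internal exon lies inside one query intron
  whose donor and acceptor both match subject junction boundaries.
- ``intron_retention``: one query exon fully spans a subject junction and
  its flanking exon ends.
- ``alt_5prime_splice`` / ``alt_3prime_splice``: a query junction shares
  one boundary with a subject junction but is shifted at the other;
  5' versus 3' is named in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, Transcript, junction_chain

__all__ = [
    "EventSet",
    "EVENT_NAMES",
    "compare_transcripts",
    "background_event_distribution",
    "event_enrichment_test",
]


@dataclass
class EventSet:
    internal_first_exon: bool = False
    internal_last_exon: bool = False
    alternative_first_exon: bool = False
    alternative_last_exon: bool = False
    exon_skipping: bool = False
    intron_retention: bool = False
    alt_5prime_splice: bool = False
    alt_3prime_splice: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def any(self) -> bool:
        return any(self.as_dict().values())


EVENT_NAMES = [f.name for f in fields(EventSet)]


def _overlap(a, b) -> bool:
    return a.start < b.end and b.start < a.end


def compare_transcripts(query: Transcript, subject: Transcript) -> EventSet:
    """Structural events of ``query`` relative to ``subject`` (same gene)."""
    if query.gene_id != subject.gene_id:
        raise ValueError(
            f"cannot compare transcripts of different genes "
            f"({query.gene_id} vs {subject.gene_id})"
        )
    ev = EventSet()
    q_chain = junction_chain(query)
    s_chain = junction_chain(subject)
    if q_chain == s_chain and (query.start, query.end) == (subject.start, subject.end):
        return ev

    strand = query.strand
    s_internal = subject.exons[1:-1]

    # terminal exons in transcript orientation
    q_first = query.exons[0] if strand == "+" else query.exons[-1]
    q_last = query.exons[-1] if strand == "+" else query.exons[0]
    s_first = subject.exons[0] if strand == "+" else subject.exons[-1]
    s_last = subject.exons[-1] if strand == "+" else subject.exons[0]

    # inner junction boundary of a terminal exon: the side facing the
    # transcript body
    def inner(exon, is_first: bool) -> int:
        if (strand == "+") == is_first:
            return exon.end
        return exon.start

    if len(query.exons) > 1:
        if any(inner(q_first, True) == inner(e, True) for e in s_internal):
            ev.internal_first_exon = True
        if any(inner(q_last, False) == inner(e, False) for e in s_internal):
            ev.internal_last_exon = True
    if not ev.internal_first_exon and not _overlap(q_first, s_first):
        ev.alternative_first_exon = True
    if not ev.internal_last_exon and not _overlap(q_last, s_last):
        ev.alternative_last_exon = True

    s_donors = {d for d, _ in s_chain}
    s_acceptors = {a for _, a in s_chain}
    for d, a in q_chain:
        if (d, a) in s_chain:
            continue
        if d in s_donors and a in s_acceptors:
            if any(d <= e.start and e.end <= a for e in s_internal):
                ev.exon_skipping = True
            continue
        shifted_acceptor = d in s_donors and any(
            sd == d and sa != a for sd, sa in s_chain
        )
        shifted_donor = a in s_acceptors and any(
            sa == a and sd != d for sd, sa in s_chain
        )
        if shifted_acceptor:
            if strand == "+":
                ev.alt_3prime_splice = True
            else:
                ev.alt_5prime_splice = True
        if shifted_donor:
            if strand == "+":
                ev.alt_5prime_splice = True
            else:
                ev.alt_3prime_splice = True

    for e in query.exons:
        if any(e.start < d and a < e.end for d, a in s_chain):
            ev.intron_retention = True
            break
    return ev


def background_event_distribution(
    pairs: list[tuple[str, str]],
    annotation: Annotation,
    n_rep: int = 20,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated null for event fractions.

    ``pairs`` lists (gene_id, target transcript id); in each of ``n_rep``
    repetitions one non-target isoform is drawn uniformly per gene and
    compared against the target, and the fraction of genes showing each
    event is recorded. Genes with fewer than 2 isoforms are excluded (the
    excluded count is stored in ``attrs['n_excluded']``). Returns a frame
    indexed by event with columns mean / sd / n_rep.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    usable = []
    excluded = 0
    for gid, target in pairs:
        others = [t.id for t in annotation.genes[gid].transcripts if t.id != target]
        if others:
            usable.append((target, sorted(others)))
        else:
            excluded += 1
    fractions = np.zeros((n_rep, len(EVENT_NAMES)))
    for r in range(n_rep):
        counts = np.zeros(len(EVENT_NAMES))
        for target, others in usable:
            pick = others[int(rng.integers(0, len(others)))]
            ev = compare_transcripts(
                annotation.transcripts[pick], annotation.transcripts[target]
            )
            counts += np.array([ev.as_dict()[name] for name in EVENT_NAMES], dtype=float)
        fractions[r] = counts / max(len(usable), 1)
    out = pd.DataFrame(
        {
            "mean": fractions.mean(axis=0),
            "sd": fractions.std(axis=0, ddof=0),
            "n_rep": n_rep,
        },
        index=pd.Index(EVENT_NAMES, name="event"),
    )
    out.attrs["n_excluded"] = excluded
    out.attrs["n_genes"] = len(usable)
    return out


def event_enrichment_test(
    observed_fraction: float,
    n_obs: int,
    background_fraction: float,
    n_bg: int,
    n_events: int = len(EVENT_NAMES),
) -> tuple[float, float]:
    """Unpooled two-proportion z-test with Bonferroni correction.

    Returns (z, adjusted p); the adjustment multiplies the raw two-sided
    p-value by the number of event categories tested, capped at 1.
    Degenerate variance on both sides yields NaN.
    """
    var = observed_fraction * (1 - observed_fraction) / n_obs + background_fraction * (
        1 - background_fraction
    ) / n_bg
    if var == 0:
        if observed_fraction == background_fraction:
            return 0.0, 1.0
        return float("nan"), float("nan")
    z = (observed_fraction - background_fraction) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p * n_events))
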