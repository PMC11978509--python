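"""Structural event vocabulary, the simulated background null and the
enrichment z-test."""

import numpy as np
import pytest

from txbench.annotation import Annotation, Gene
from txbench.events import (
    EVENT_NAMES,
    background_event_distribution,
    compare_transcripts,
    event_enrichment_test,
)
from txbench.simulate import SimulationConfig, generate_annotation
from .conftest import make_tx


def test_identity_comparison_is_empty(toy_annotation):
    for tx in toy_annotation.transcripts.values():
        assert not compare_transcripts(tx, tx).any()


def test_different_genes_rejected(toy_annotation):
    with pytest.raises(ValueError):
        compare_transcripts(
            toy_annotation.transcripts["TA1"], toy_annotation.transcripts["TB1"]
        )


def test_exon_skipping(toy_annotation):
    # TA3 = E1,E3 with a junction joining E1's donor to E3's acceptor
    ev = compare_transcripts(
        toy_annotation.transcripts["TA3"], toy_annotation.transcripts["TA1"]
    )
    assert ev.exon_skipping
    assert not ev.internal_first_exon and not ev.alternative_first_exon


def test_internal_first_exon():
    subject = make_tx("S", "G", [(0, 100), (200, 300), (400, 500)])
    query = make_tx("Q", "G", [(200, 300), (400, 500)])
    ev = compare_transcripts(query, subject)
    assert ev.internal_first_exon and not ev.alternative_first_exon
    # mirrored on the minus strand: genomically-last exon is the 5' end
    subject_m = make_tx("Sm", "Gm", [(0, 100), (200, 300), (400, 500)], strand="-")
    query_m = make_tx("Qm", "Gm", [(0, 100), (200, 300)], strand="-")
    ev = compare_transcripts(query_m, subject_m)
    assert ev.internal_first_exon and not ev.internal_last_exon


def test_internal_last_exon(toy_annotation):
    ev = compare_transcripts(
        toy_annotation.transcripts["TA2"], toy_annotation.transcripts["TA1"]
    )
    assert ev.internal_last_exon and not ev.alternative_last_exon


def test_alternative_first_and_last_exon():
    subject = make_tx("S", "G", [(1000, 1100), (1200, 1300), (1400, 1500)])
    query = make_tx("Q", "G", [(700, 800), (1200, 1300), (1600, 1700)])
    ev = compare_transcripts(query, subject)
    assert ev.alternative_first_exon and ev.alternative_last_exon
    assert not ev.internal_first_exon and not ev.internal_last_exon


def test_intron_retention():
    subject = make_tx("S", "G", [(0, 100), (200, 300)])
    query = make_tx("Q", "G", [(0, 300)])
    assert compare_transcripts(query, subject).intron_retention


def test_alternative_splice_sites_strand_aware():
    subject = make_tx("S", "G", [(0, 100), (200, 300), (400, 500)])
    # donor of first junction shifted: alt 5' on plus strand
    q_donor = make_tx("Qd", "G", [(0, 80), (200, 300), (400, 500)])
    ev = compare_transcripts(q_donor, subject)
    assert ev.alt_5prime_splice and not ev.alt_3prime_splice
    # acceptor shifted: alt 3' on plus strand
    q_acc = make_tx("Qa", "G", [(0, 100), (220, 300), (400, 500)])
    ev = compare_transcripts(q_acc, subject)
    assert ev.alt_3prime_splice and not ev.alt_5prime_splice
    # identical coordinates on the minus strand swap the labels
    subject_m = make_tx("Sm", "Gm", [(0, 100), (200, 300), (400, 500)], strand="-")
    q_donor_m = make_tx("Qm", "Gm", [(0, 80), (200, 300), (400, 500)], strand="-")
    ev = compare_transcripts(q_donor_m, subject_m)
    assert ev.alt_3prime_splice and not ev.alt_5prime_splice


def test_identity_sweep_on_simulated_annotation():
    ann, _ = generate_annotation(SimulationConfig(n_genes=30, seed=4))
    for tx in ann.transcripts.values():
        assert not compare_transcripts(tx, tx).any()


def test_background_two_isoform_gene_degenerate():
    """With a single alternative isoform every draw is identical: sd = 0."""
    ann = Annotation(
        [
            Gene(
                "G",
                [
                    make_tx("T1", "G", [(0, 100), (200, 300), (400, 500)]),
                    make_tx("T2", "G", [(200, 300), (400, 500)]),
                ],
            )
        ]
    )
    bg = background_event_distribution([("G", "T1")], ann, n_rep=20, seed=0)
    assert (bg["sd"] == 0).all()
    assert bg.loc["internal_first_exon", "mean"] == 1.0


def test_background_determinism_and_exclusions(toy_annotation):
    pairs = [("GA", "TA1"), ("GC", "TC1")]
    a = background_event_distribution(pairs, toy_annotation, n_rep=10, seed=7)
    b = background_event_distribution(pairs, toy_annotation, n_rep=10, seed=7)
    assert (a["mean"] == b["mean"]).all()
    assert a.attrs["n_excluded"] == 1  # single-isoform GC


def test_background_mean_matches_exhaustive_enumeration(toy_annotation):
    """3-isoform gene: at high repetition count the mean event fraction
    approaches the average over both alternatives."""
    pairs = [("GA", "TA1")]
    bg = background_event_distribution(pairs, toy_annotation, n_rep=2000, seed=1)
    exhaustive = {}
    for name in EVENT_NAMES:
        vals = [
            getattr(
                compare_transcripts(
                    toy_annotation.transcripts[t], toy_annotation.transcripts["TA1"]
                ),
                name,
            )
            for t in ("TA2", "TA3")
        ]
        exhaustive[name] = np.mean(vals)
    for name in EVENT_NAMES:
        assert bg.loc[name, "mean"] == pytest.approx(exhaustive[name], abs=0.05)
    # means lie in the convex hull of per-draw values (0/1 fractions here)
    assert bg["mean"].between(0, 1).all()


def test_event_enrichment_test():
    z, p = event_enrichment_test(0.3, 100, 0.3, 200)
    assert z == 0.0 and p == 1.0
    z, p = event_enrichment_test(0.5, 200, 0.3, 200, n_events=8)
    raw_var = 0.5 * 0.5 / 200 + 0.3 * 0.7 / 200
    assert z == pytest.approx(0.2 / np.sqrt(raw_var))
    from scipy import stats

    raw_p = 2 * stats.norm.sf(abs(z))
    assert p == pytest.approx(min(1.0, raw_p * 8))
    z, p = event_enrichment_test(0.0, 50, 1.0, 50)
    assert np.isnan(z) and np.isnan(p)
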