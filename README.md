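# txbench

Transcript-level comparison analytics for long-read versus short-read
RNA-seq: read-to-transcript classification, EM quantification,
major-isoform concordance, coverage and diversity statistics, in-silico
read fragmentation, structural isoform-event comparison and spike-in
evaluation — together with a seeded synthetic-data generator so every
stage runs and is testable without any sequencing libraries.

It is written for people who compare RNA-seq library preparations
(Nanopore direct RNA / direct cDNA / PCR cDNA, PacBio IsoSeq, Illumina)
at the isoform level and want the comparison analytics as tested,
reusable code.

## What it computes

**Read classification.** A read with splice-junction chain
J(r) = ((d₁,a₁),…,(dₖ,aₖ)) is a *full splice match* (FSM) to transcript t
when J(r) = J(t) exactly, and *partial* when J(r) is a non-empty
consecutive sub-chain of J(t) (junction-free reads are FSM to a
single-exon transcript containing them and partial to a multi-exon
transcript when contained in one exon). Reads sharing a chain, label and
compatible-transcript set form a *read class* with count n_c.

**Quantification.** Abundances θ solve the EM fixed point over read
classes: the E-step splits n_c across compatible transcripts ∝ θ_t
(∝ θ_t / ℓ̃_t in fragment mode, with effective length
ℓ̃_t = ℓ_t − L + 1), the M-step renormalises; estimated counts always sum
to the assigned count. CPM = counts/total × 10⁶; TPM additionally divides
by ℓ̃_t.

**Major isoforms.** Per gene and technology, the isoform with the highest
mean expression across replicates. Comparing long-read (LR) and
short-read (SR) majors partitions transcripts into major-shared,
major-LR-specific, major-SR-specific and minor, with per-category
Spearman/MAE agreement on log₂(CPM+1).

**Coverage and diversity.** 100-bin relative coverage per transcript
(deletion-spanned bases count as covered, bins normalised by the maximum
bin); cumulative read fraction over genes ranked by expression or length;
a length-adjusted gene-coverage ratio Σ n_c·(w_c/L_max) / Σ n_c with an
unequal-variance two-proportion z-test.

**In-silico fragmentation.** Each long read with mapped length m ≥ 150
yields N = ⌊m/150⌋ fragments with starts uniform on
[aln_start, aln_end − 150]; fragment sequences are reference substrings
(error-corrected by construction).

**Events and spike-ins.** Pairwise structural events (internal/alternative
first and last exon, exon skipping, intron retention, alternative 5′/3′
splice sites) decided from junction chains; a 20-repeat
random-alternative background null with Bonferroni-corrected two-sided
z-tests; spike-in expected CPM (fraction × relative concentration × 10⁶)
scored with Spearman, MAE, MRAD, MRD, RMSE and R².

## Worked example

Simulate a dataset and run the analyses (each script prints what it
found and writes a table under `results/`):

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_classify_reads.py
python analysis/06_fragmentation_study.py --seed 1
```

With seed 1 the classification table shows the expected protocol
behaviour — full-length IsoSeq-like reads are all FSM and uniquely
assigned, truncated direct-RNA-like reads less so, and 150-bp fragments
cover almost no junctions:

```
               n_reads  assigned_fraction  fsm_fraction  unique_fraction  mean_junctions_per_read
IsoSeq-like      30000                1.0         1.000            1.000                    4.782
PCR-cDNA-like    30000                1.0         0.887            0.960                    3.637
dRNA-like        30000                1.0         0.697            0.893                    3.108
dcDNA-like       30000                1.0         0.771            0.919                    3.305
short            90000                1.0         0.014            0.486                    0.537
```

and the 20-seed fragmentation study reports

```
ordering shared >= LR-specific >= SR-specific holds in 95% of seeds;
Spearman vs short reads: 0.762 before fragmentation, 0.817 after
```

i.e. agreement between original and fragmented long-read estimates is
highest for shared major isoforms and lowest for short-read-specific
ones, and fragmenting the long reads moves their estimates toward the
independently simulated short-read estimates.

There is also a thin CLI (`txbench simulate|classify|quantify|fragment|run …`)
over the same library functions.

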