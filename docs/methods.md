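# Methods

## Scope and model

txbench re-implements the transcript-level comparison analytics used to
contrast long-read and short-read RNA-seq protocols: classify reads
against an annotation, quantify transcripts, identify per-gene major
isoforms per technology, measure coverage bias and library diversity,
fragment long reads in silico, compare isoform structures, and score
quantification against spike-in ground truth. Upstream steps
(basecalling, alignment, junction correction) and external quantifiers
are out of scope: the package consumes alignments — transcriptome-space
BAM or a plain TSV (read_id, transcript_id, start, end) — and assumes
junctions have been corrected upstream, which is why junction comparison
is exact by default (an optional ±k bp tolerance exists but is off).

Coordinates are 0-based half-open internally; GTF I/O converts from/to
1-based closed. Junction identity is the genomic (donor_end,
acceptor_start) pair, and chains stay in ascending genomic order on both
strands, so classification is a pure chain comparison independent of
strand bookkeeping.

## Read classification

FSM requires exact equality of the read's chain with a transcript's
complete chain. "Partially contained" is interpreted as *consecutive*
sub-chain containment plus span containment within the transcript's
extent — arbitrary subsets would accept biologically incompatible
splicing patterns. The FSM/partial definitions address spliced reads;
for junction-free reads this package labels containment in a single-exon
transcript FSM and containment within one exon of a multi-exon
transcript partial, with a `spliced_only` mode that leaves junction-free
reads unassigned for users who prefer the strict reading. Read classes
group reads by (chromosome, chain, label, compatible set), which makes a
class's compatibility identical to each member's by construction; class
width is the genomic span of the class (a `blocks` width mode, summing
block widths instead, serves the gene-coverage ratio's alternative
reading).

## EM quantifier

A deliberately minimal quantifier over read-class compatibility: uniform
initialisation, E-step proportional to current abundance (divided by
effective length ℓ − L + 1 in fragment mode), M-step renormalisation,
convergence at relative L1 change < 1e-8 or 1,000 iterations,
deterministic throughout (no seed needed). Counts are conserved exactly
up to floating point. Long-read mode applies no length correction — a
full-length molecule is one count regardless of length — while fragment
mode must, because fragment counts scale with length; this mirrors the
count-vs-fragment-density distinction between long- and short-read
quantifiers. Both CPM and TPM are emitted so either convention can be
selected per analysis (short-read comparisons conventionally use TPM).

Near-confounded structures (a subset isoform sharing almost all of its
parent's fragmentable positions) make fragment-mode EM converge slowly;
the non-convergence warning is informational, and the resulting residual
mass on the subset isoform is the identifiability limit any quantifier
faces on such structures, not a numerical defect.

## Coverage, diversity, gene-coverage ratio

Coverage counts deletion-spanned bases as covered (blocks merge `D`
operations; only `N` splits blocks). Profiles use 100 integer bins
(bin i covers [⌊iL/100⌋, ⌊(i+1)L/100⌋)); transcripts shorter than 100
bases or with zero coverage are excluded and counted. Diversity curves
are cumulative read fractions over ranked genes; tied counts produce a
linear segment across the tied rank span, the interpolation choice for
ties. The per-protocol summary is the median curve across samples, and
the headline statistic is the fraction attributed to the top-k genes
(k = 1,000 at study scale; the desk-scale analyses use k = 50 because the
synthetic genome has 200 genes). The gene-coverage ratio weights each
read class by width/L_max (capped at 1, since a genomic span can exceed
the summed exon length of the longest isoform) and is meant for genes
above a 30-CPM gate in all compared protocols; its z-test treats the
ratio as a proportion with unpooled variance r(1−r)/n, n the gene's read
count per protocol.

## In-silico fragmentation

Only the bound N ≤ mapped/150 is inherent to the procedure; this package
fixes N = ⌊mapped/150⌋ deterministically and offers `n_rule="uniform"`
(N ~ U{1, ⌊mapped/150⌋}) for sensitivity analysis. Mapped length is the
alignment span on the transcript, because start positions are defined on
the alignment interval. Reads under 150 bp are skipped and counted,
never an error. Fragments are single-end reference substrings — an
error-corrected simulation by construction — and the 5′-anchored
trimming series (150→50 bp in 25-bp steps) covers the short-read
read-length sensitivity analysis.

## Structural events

The event vocabulary is decided from exon/junction coordinates alone,
strand-aware: internal first/last exon (query terminal exon shares its
inner boundary with a subject internal exon), alternative first/last
exon (non-overlapping terminals, no internal match), exon skipping
(subject internal exon inside a query intron whose boundaries match
subject junctions), intron retention (query exon spans a subject
junction and flanks), and alternative 5′/3′ splice sites (one shared,
one shifted junction boundary, named in transcript orientation). The
background null redraws, 20 times, one random non-target isoform per
gene and records event fractions; genes with a single alternative give a
degenerate null (sd 0) and single-isoform genes are excluded and
counted. Enrichment is an unpooled two-proportion z-test,
Bonferroni-corrected across the eight events.

## Spike-ins

Expected CPM is spike_fraction × relative concentration × 10⁶ (the total
read count cancels on the CPM scale). The metric suite operates on
log2(CPM+1). The relative metrics' denominators are not universal; this
package anchors them to the expected value (error relative to truth)
with a `rel_denominator="mean"` option for the symmetric convention, and
reports both interpretations side by side where needed.

## Synthetic-data generator

The generator defines the study conditions, with one master seed and
fixed per-stage stream offsets:

- **Genome**: non-overlapping genes on one synthetic chromosome; exons
  120–400 bp, introns 60–250 bp, 1–4 isoforms per gene. A configurable
  fraction of multi-isoform genes carries a *subset isoform* — a
  consecutive exon sub-range of the longest isoform missing one terminal
  exon, so its junction chain is a strict consecutive sub-chain (the
  structure behind the internal first/last-exon pattern of major-isoform
  disagreement). Subset isoforms get near-zero true usage (multiplier
  0.005) by default: experimentally, short-read-specific major isoforms
  of this type are detected at much lower concentrations than the
  long-read-specific majors, so the generator treats them as genuinely
  minor.
- **Expression**: gene abundance log-normal on the CPM scale
  (μ = 3, σ = 1.5 in log space), isoform usage Dirichlet (α = 1.5),
  multiplicative log-normal replicate noise (σ = 0.15), per-sample
  renormalisation to 10⁶.
- **Protocols**: direct-RNA-like reads truncate with probability 0.4,
  3′-anchored (sequencing starts at the poly(A) tail); direct-cDNA-like
  0.3; PCR-cDNA-like 0.15 with sampling weight CPM^1.1 (concentration
  bias toward top-expressed genes); IsoSeq-like full-length with a
  logistic length weight (midpoint 1 kb) depleting short transcripts.
  Short-read data are 150-bp fragments sampled ∝ CPM × (ℓ − 149) with
  uniform starts. Spike-in reads are full-length, multinomial on the mix's
  relative concentrations.

The generator produces error-free transcriptome-space alignments — no
base errors, quality scores, poly(A) tails or genome-space mapping — so
passing tests demonstrate the analytics, not robustness to alignment
noise. Mapping ambiguity, the phenomenon under study, is fully present.

## Desk-scale experiments

Two canned experiments (txbench.experiments) fix problem sizes chosen so
each runs in minutes on one CPU:

- **Parameter recovery**: 200 genes, 2–4 isoforms each, 10⁵ unbiased
  full-length long reads, no subsets. Checks Spearman(true, estimated
  CPM) and recovery of true major isoforms among genes with a ≥2-fold
  usage gap.
- **Fragmentation study**: per seed, 250 genes (2–3 isoforms, 80% of
  multi-isoform genes with a subset isoform), one unbiased long-read
  sample of 15,000 reads and one independent short-read sample of 45,000
  fragments; majors and categories from these two samples; the long-read
  sample is then fragmented (150 bp, floor rule) and re-quantified in
  fragment mode. Reported over 20 seeds: the fraction of seeds with
  per-category agreement ordered shared ≥ LR-specific ≥ SR-specific, and
  the Spearman of long-read estimates against the short-read estimates
  before vs after fragmentation.

## Known limitations

- With error-free fragments and this exact EM, fragmentation inflates
  truly-silent subset isoforms (they gain substantial estimated counts)
  but usually not past the expressed isoforms, so data-driven
  major-isoform disagreement at desk scale arises mostly from fragment
  ambiguity among expressed isoforms; the internal-exon event signature
  is therefore demonstrated on the planted subset-vs-parent comparison
  (analysis script 07), where it is unambiguous, rather than claimed
  from the data-driven majors.
- Event fractions on real data depend on the comparing implementation's
  exact definitions; this package fixes its own deterministic
  definitions and validates them on constructed cases, not against
  external numeric event percentages.
- The annotation-matching and biotype filters reproduce the documented
  filtering procedure and are tested on constructed annotations; running
  them on a full Ensembl release requires downloading that release.
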