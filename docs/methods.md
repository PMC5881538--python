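# Methods

circprofiler analyses rRNA-depleted, single-end RNA-seq with circular RNAs in
mind. This note documents the models and procedures it implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Pipeline overview

Reads flow through eight stages, each exchangeable through files:

1. **QC** — raw reads become clean reads by 3' adaptor trimming and two
   fraction filters.
2. **Linear alignment** — a k-mer seed-and-extend aligner maps each clean
   read full-length to the genome, contiguously or split across one
   annotated intron; everything else enters the unmapped pool.
3. **Backsplice detection** — local segment matches of unmapped reads are
   paired under the head-to-tail rules, refined by splice-site strength, and
   aggregated into circRNA calls.
4. **Quantification** — all unmapped reads are realigned to pseudo-circular
   junction constructs; junction-spanning reads are counted per circle and
   sample.
5. **Gene counting** — union-exon, strand-aware counts for mRNA and lncRNA.
6. **Differential expression** — size factors, NB dispersions, an exact test,
   BH correction and the fold-change/FDR filter, applied uniformly to mRNA,
   lncRNA and circRNA tables.
7. **Enrichment** — one-sided Fisher tests against user-supplied gene sets,
   GO trees over a term DAG, pathway networks with Jaccard edges.
8. **Co-expression networks** — per-condition Pearson networks, degree
   centrality, W-cores and differential core regulators.

## Read QC

A read is removed when, after adaptor trimming, more than 5% of its bases
are N, or more than 20% of its bases have Phred quality below 13, or it is
shorter than `min_length_after_trim` (default 20 nt). Both fraction rules
use strict inequality — a read at exactly 5% N and exactly 20% low-quality
bases is kept. Trimming finds the leftmost read suffix matching a prefix of
the adaptor with at least 5 exact bases (0 mismatches by default). The
filters are evaluated on the trimmed read; the report tallies removals per
rule so that kept + removed always equals the input count.

## Linear alignment

The built-in aligner exists so the pipeline needs no external binary at desk
scale; it is not a reimplementation of any production aligner. A k = 15
exact k-mer index is built over both strands (minus-strand loci are stored
under the reverse-complemented k-mer). For each read and orientation,
non-overlapping seeds propose diagonals; a read is mapped iff some placement
— contiguous, or split at exactly one annotated intron — matches full-length
with at most `max_mismatches`. The best placement minimises
(mismatches, chromosome, position, strand), which makes multi-mapper
resolution deterministic.

`max_mismatches` defaults to 0 because the default simulated reads are
error-free. This is load-bearing for exact circRNA quantification: with a
mismatch budget, a junction read whose overhang is only a few bases can be
absorbed into a linear alignment by chance (a 6-base overhang matches a
random genomic continuation within 2 mismatches ~4% of the time), removing
it from the unmapped pool. With substitution errors switched on in the
simulator, set `max_mismatches` to 2 and expect quantification to be nearly,
not exactly, complete.

Reads spanning two introns are beyond the one-intron contract and fall into
the unmapped pool; detection explicitly recognises and ignores them (below).

Alignments can also be ingested from SAM: primary unclipped records become
linear alignments, records with soft clips of at least 18 aligned bases and
supplementary records become segment matches, flag-4 records join the
unmapped pool.

## Backsplice detection

**Candidate generation.** Unmapped reads are decomposed into maximal
near-exact local matches (segments), merging index seeds per diagonal and
extending through at most one mismatch per 25 aligned bases; segments with
score (length − mismatches) below 18 are discarded. Within one read, every
segment pair on the same chromosome and strand, spanning at most 1 Mb, whose
genomic order is the *reverse* of its read order, yields a raw junction
candidate: the acceptor at the genomically-upstream segment's start, the
donor at the downstream segment's end. Pairs in forward order are ordinary
splices and are never candidates. Small read-interval overlaps between the
two segments (chance extension past the junction, up to 10 nt) are trimmed
onto the later segment; gaps up to 3 nt (errors) are bridged.

**Short-overhang rescue.** A junction read whose overhang on one side is
shorter than 18 nt produces only one segment, so pairing alone would miss
it. For each long anchor segment with an unaligned remainder of at least
`min_overhang` (6) but fewer than 18 bases, the remainder is searched for
exactly within 1 Mb of the anchor on the side that reverse order requires;
every occurrence yields a raw candidate, and the splice-score filter removes
the spurious ones. Before rescue, the read is tested for a *forward*
explanation: if it can be walked left and right from the anchor exactly,
jumping forward across annotated introns, it is a linear (multi-)spliced
read and is excluded. This keeps two-intron linear reads — unmappable by the
one-intron aligner — from fabricating junctions, and makes discovery
complete for overhangs ≥ 6 on error-free reads.

**Splice-site scoring.** Junction strength is scored with a position-weight
matrix: a 9-nt donor window (3 exonic + 6 intronic bases) and a 23-nt
acceptor window (20 intronic + 3 exonic), log2-odds against the genome's
base composition, summed over positions; a window matching the background
exactly scores 0 and a window containing N scores −inf. The default
matrices are estimated from the annotation's own splice sites with add-one
smoothing; matrices can also be loaded from TSV. The scorer is a pluggable
operating point, not a claim of equivalence with any external
maximum-entropy model; on the synthetic genome true backsplice flanks score
roughly 30–37 bits while random windows score deeply negative, so the
reporting threshold of 10 separates them cleanly.

**Refinement.** When the sequence flanking a junction repeats, the junction
position is ambiguous: read and genome stay consistent under a *joint* shift
of (acceptor, donor). Each raw candidate is slid over shifts in [−10, +10];
a shift is admissible when the supporting read still matches the genome on
both sides of the shifted junction within 2 mismatches, and the admissible
shift with the highest donor + acceptor score wins, ties going to the
smallest acceptor position.

**Calling.** Refined candidates are aggregated by (chrom, strand, acceptor,
donor). A read supporting several junctions counts only toward the one with
the highest score. A junction is reported iff it has at least 2 distinct
supporting reads *and* a splice score of at least 10 — both thresholds
inclusive. Host genes are same-strand genes whose span contains the
junction; the exonic length sums the first host's exons inside the circle.
Calls are compared with a known-junction BED by exact
(chrom, strand, start, end) identity.

## Quantification

For each call a junction construct of length 2·(L − min_overhang) is built
by concatenating the circle's last (L − min_overhang) bases to its first
(L − min_overhang) bases, where L is the read length; the circle sequence is
assembled from the host gene's annotated exons inside the circle (genomic
span as fallback), and circles shorter than one arm wrap around. The
construct length guarantees that any read satisfying the overhang rule fits
inside it, so counting reduces to mismatch-limited substring placement. A
read counts for a circle iff some placement (either orientation) covers the
construct midpoint with at least 6 bases on both sides within 2 mismatches;
each read counts for at most one circle (fewest mismatches, ties to the
lexicographically smallest id). Unmapped pools are processed per sample,
yielding the circ × sample table that feeds DE.

Because simulated junction reads are drawn uniformly over positions obeying
the overhang constraint, the counted reads equal the simulated reads exactly
at error rate 0 — the package's central exactness check.

## Differential expression

The classic single-factor NB testing recipe, implemented here:

- **Size factors** — median over features (nonzero in all samples) of
  count/geometric-mean ratios. Factors are defined up to a common scale;
  scaling one sample by c multiplies its factor *relative to any other
  sample* by exactly c.
- **Dispersion** — method-of-moments α = max(0, (s² − μ)/μ²) from
  normalized counts, with s² pooled within conditions, then shrunk against a
  least-squares trend α ~ a0 + a1/μ by taking the per-feature **maximum** of
  raw and trend. The maximum rule is deliberately conservative: at n = 3 per
  condition it protects the type-I error (measured null fraction at
  FDR < 0.05: ~10⁻⁴ across 20 simulations) at some cost in power (still
  ≥ 95% for 8-fold spikes at base mean ≥ 100).
- **Exact test** — conditional on a feature's total count, the two-sided NB
  exact test sums the probabilities of all splits at most as likely as the
  observed one, under NB laws with condition-scaled means (pooled mean
  estimate) and the feature's dispersion. As α → 0 this collapses exactly to
  the two-sided binomial test, which the test suite uses as an oracle.
- **Thresholds** — up iff FC > 2 and FDR < 0.05; down iff FC < 0.5 and
  FDR < 0.05; strict inequalities. FC is the tumor/normal ratio of
  normalized means; zero-in-one-condition features carry ±inf/0 symbolically
  and rely on the FDR criterion. BH correction is delegated to statsmodels
  and cross-checked against the step-up definition.

## Enrichment and networks

Fisher enrichment is the hypergeometric upper tail P[X ≥ k] per term, BH
corrected across terms; terms without background annotation are skipped and
query genes missing from the background are an error, not a warning. The GO
tree induces, over a user-supplied DAG, the significant terms (P < 0.01) and
all their ancestors, annotated by the direction-partitioned queries. The
pathway network joins enriched pathways sharing DE genes with Jaccard
weights; "core pathways" are the top-degree nodes.

Condition networks use Pearson correlation on size-factor-normalized
log2(x+1) counts, edges kept at |r| ≥ 0.9 and BH-adjusted t-test p ≤ 0.05
(df = n − 2; hence the hard requirement of ≥ 3 samples). The W-core is the
maximal subgraph in which every node keeps at least W neighbours — exactly
the graph-theoretic k-core, computed with networkx's pruning and verified in
tests by exhaustive subset enumeration. Core regulators rank nodes by
|degree_A − degree_B| over the shared node universe (missing node = degree
0), ties by larger maximum degree, then id.

## The synthetic-data generator

The generator emulates the features downstream stages assume, at desk scale:

- 3 chromosomes × 100 kb, 40 genes of 3–6 exons (80–300 nt) and introns
  (200–1500 nt), ~70% mRNA / 30% lncRNA, CDS/UTR structure on mRNAs.
- Every intron carries a sampled near-consensus donor/acceptor window
  (GT..AG guaranteed), so a PWM trained on the annotation is informative.
- 20 exon-bounded circles on internal exon runs (so both backsplice flanks
  are true splice sites), one host gene carrying two circles, each circle
  with 2–30 junction reads placed uniformly over positions with ≥ 6 nt
  overhang on both sides, drawn from the wrap-around circular sequence.
- Linear reads uniform over spliced transcripts (Poisson depth per
  transcript, or an exact total); optional noise reads that are random,
  N-laced (10% N) or low-quality-tailed (25% of bases at Q10) to exercise
  each QC rule; constant Q35 elsewhere to isolate filter behaviour.
- NB count matrices with log-normal base means, a common dispersion, and
  multiplicative fold-change spikes in the tumor condition (spiked features
  get base means of 100–500 so power statements are about expressed genes);
  read-level spikes are also supported for end-to-end DE runs.
- Read names encode origin (`lin`/`circ`/`noise`, source, position) so every
  read is auditable without side files; all outputs are pure functions of
  the configuration, seed included.

What it does **not** emulate — and what passing tests therefore do not show
about real data: indels and position-dependent error profiles, rRNA
contamination, coverage biases (GC, 3' decay), overlapping genes and
alternative isoforms, intronic/lariat-derived circles, rolling-circle
amplification, pooling variance across tissues within one library, and the
scale of a real genome (repeat-induced multi-mapping is much milder here).

## Problem sizes and runtime

The shipped test suite and the acceptance script use the study-scale
defaults above (≈ 2,400 reads for the recovery scenario; 51,000 reads for
the specificity scenario; 1,000 features × 20 simulations for DE
calibration; a 16-gene, 6-sample study for the end-to-end runs). The whole
suite runs in about a minute on one core; the acceptance script in under
half a minute.

## Known limitations

- The aligner has no indel support and no base-quality-aware scoring; both
  are out of scope by design.
- Detection sensitivity for reads with substitution errors in a short
  overhang is limited: rescue requires an exact remainder match. Support
  counting by realignment (quantification) is more tolerant (2 mismatches).
- The splice-score threshold of 10 is an operating point on the trained-PWM
  scale; porting it to another scorer requires recalibration on annotated
  true sites versus background.
- The exact test conditions on raw summed counts, so results are invariant
  under library-size differences only through the size factors, not under
  arbitrary rescaling of a single sample's integer counts.
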