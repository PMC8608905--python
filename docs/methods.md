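# Methods

This note documents the models and procedures implemented in
`isoforge`, the defaults they use, and what the synthetic fixtures do
and do not establish about real data.

## Coordinates and junction-chain identity

All positions are 0-based, half-open on the forward genomic strand
(GTF I/O converts to/from 1-based inclusive).  A multi-exon isoform's
identity is its ordered splice-junction chain — chromosome, strand and
the intron coordinates — never its end coordinates, because 5′ RNA
degradation and imprecise transcription starts make long-read TSS
unreliable while junctions are read accurately.  Mono-exon chains
deliberately receive per-read sentinel keys so that key-based grouping
can never merge them; all mono-exon merging goes through same-strand
span overlap instead.

## Collapsing model

Within a sample:

1. multi-exon reads group by junction chain; the group's TSS is the
   most upstream supported 5′ end, the TTS the most downstream 3′ end,
   and all supporting ends are retained;
2. a grouped isoform whose chain equals a contiguous 3′-terminal run of
   a longer isoform's junctions (in transcript orientation: genomically
   last junctions on `+`, first on `-`) **and** whose span is contained
   in the longer isoform's span is absorbed as a 5′-truncated fragment.
   "Compatible" is not self-defining; the suffix-plus-containment rule
   is this package's formalization — containment stops a read that
   extends 5′ past the longer isoform from being called its fragment.
   A fragment compatible with several longer isoforms is linked to all
   of them (ambiguous), not dropped: the reads still support the locus,
   they just cannot be attributed, so they count for no isoform's
   PBcount;
3. mono-exon reads form connected components under same-strand overlap
   and never merge into multi-exon isoforms.

Across samples, isoforms merge only on identical junction chains
(mono-exon: overlap components again).  A truncated chain that survived
in one sample is *not* absorbed by a longer chain from another sample:
observing the shorter chain as the longest form in some sample is
treated as evidence of a genuine shorter transcript.  Gene groups are
connected components under shared-junction or same-strand exonic
overlap; isoform ids are `PB.<gene>.<n>`.

Detection of an isoform in a sample requires non-truncated support: a
read whose full junction chain matches (multi-exon) or a mono-exon read
contained in the isoform's span.  PBcount per sample is the sum of
full-length (FL) counts of reads linked uniquely to the isoform;
ambiguous links contribute nowhere, so the per-sample sum of PBcounts
never exceeds the sample's total FL count, with equality exactly when
no read is ambiguous.

All tie-breaks (output order, id assignment) are lexicographic on
(chromosome, start, junction key), making results independent of read
and sample input order.

## Prefilters

Alignments are kept only with mapping quality strictly greater than 50
(configurable); alignment gaps ≥ 20 nt count as introns, shorter ones
as deletions bridged into exons (configurable; aligners differ in how
they encode micro-introns).  The major-isoform prefilter keeps, per
gene, isoforms that rank 1st or 2nd by PBcount in at least one sample
(competition ranking, so ties share a rank) *and* have PBcount ≥ 5 in
every sample, up to 10 per gene in descending total PBcount; a gene
with no qualifier rescues its single top-PBcount isoform.  The
every-sample reading of the floor is strict; a `require_all_samples=False`
switch relaxes it to a total-count floor.  The relative-expression
filter drops isoforms whose share of their gene's expression, averaged
across samples, is below 0.1 (a share of exactly 0.1 is kept); the
averaging choice is ours — per-sample shares with 0/0 treated as 0.

## Classification ladder

Multi-exon queries: FSM (junction chain equals a reference transcript's
chain) > fusion (same-strand exonic overlap with ≥ 2 reference genes
and a junction whose two ends fall in different genes) > ISM (chain is
a contiguous subchain) > NIC (every donor and acceptor annotated,
strand-aware, but the chain itself not) > NNIC (≥ 1 novel donor or
acceptor).  The ladder order is a documented choice; a chain that is an
ISM of one transcript is reported as ISM even if it would be NIC
relative to another.  Mono-exon queries take genic (same-strand exon
overlap) > genic-intron (contained in an annotated intron) > antisense
(gene overlap on the opposite strand only) > intergenic; mono-exon
FSM/ISM are not assigned.  A same-strand gene-span overlap that touches
neither exon nor a containing intron falls back to genic.

Junction motifs read the first and last two intronic bases
(reverse-complemented on `-`); canonical classes are GT-AG, GC-AG,
AT-AC.  Artifact labels: TP ⇔ FSM; TN ⇔ at least one junction that is
both novel and non-canonical; the built-in filter removes TN isoforms.
The labels can also train an external classifier — no random-forest
filter is trained here.

## Exact Fisher test and specificity calls

`fisher_two_tailed` enumerates, with exact integer arithmetic, all 2×2
tables with the observed margins and sums the hypergeometric point
masses not exceeding the observed one (ties compare integers, so no
floating-point slack is needed; the result is converted from an exact
rational).  Detection-matrix categories, applied in order: *common* —
detected in more than half of the samples of both groups (strict >, so
5 of 8 and 8 of 14); *unique* — exactly one detection overall;
*subtype-specific* — all detections in one group and Fisher p < 0.05
for (k, n₁−k) vs (0, n₂); *other* — the rest.  With 8 vs 14 samples the
direct test turns significant at 3 and 7 detections; an optional
per-group minimum-count override (`min_detected`) replaces the test
with an explicit "more than m samples" threshold for studies that state
their cutoffs that way.  Fold-change ranking uses
log₂((m_own+ε)/(m_other+ε)) of group-mean TPM with ε = 0.01 (the
truncation of |log₂FC| at 10 implies some zero-handling; a fixed small
pseudocount is ours), reported clipped to ±10, top 100 by magnitude.

## Fusion-transcript analysis

Chimeric reads are reads with 2–3 alignment segments, ordered by read
coordinate (= transcript 5′→3′).  Each inter-segment boundary is a
fusion point with a few bp of alignment uncertainty.  Refinement scans
joint offsets δ ∈ [−10, +10] applied to both sides simultaneously —
moving the breakpoint along the read, which preserves the transcript
sequence length (moving the two sides independently would instead
change the read sequence).  A candidate offset is
canonical when the two bases transcript-downstream of the 5′ break and
the two bases upstream of the 3′ break form GT-AG, GC-AG or AT-AC
(strand-aware).  Exactly one candidate ⇒ adopt it, mark the point
spliced; zero or several ⇒ keep the raw position, unspliced.  The
10 bp radius operationalizes "several bp" of uncertainty.

Linking: a fusion point links to an SV when both of its genomic sides
are within w of the SV's two sides (both pairings tried; chromosomes
must match), w = 100,000 bp for spliced points (the genomic break may
be an intron away from the spliced fusion point) and 100 bp for exonic
points; "within" is inclusive (≤ w).  Ties resolve to the minimal
summed distance.  Fusion-specific junctions are intra-segment junctions
absent from both the reference and the non-chimeric cohort junction
sets; a read carrying such a junction with a non-canonical motif is
discarded as a likely artifact.  Fragment contexts reuse the
classification primitives; a breakpoint side inside an exon is
constitutive-exonic if that position is exonic in every transcript of
the gene, else alternative-exonic; non-genic fragments give non-genic
sides.  Three-segment reads are reported as double-hop (both points
linked), candidates (exactly one linked — the unlinked point is emitted
for external breakpoint search, which is out of scope here), or
rejected (none linked).

## Read simulator

Sampling weight of transcript i is relative_expression·length,
normalized — SMRT cDNA yield is length-dependent and the simulator
reconstitutes that.  Decay: shortening s ~ Gamma(shape, scale) in
transcript coordinates, removed from the 5′ end; if the remainder is
below 200 nt (the library-prep minimum sequence length) the template is
redrawn, up to 100 attempts, then the read is emitted unshortened.  The
3′ end is positionally exact — long-read TTS calls carry little error —
and no 3′ decay is modeled.  Errors: independent per-base substitution
(to a uniformly different base), insertion (uniform base appended after
the position) and deletion, each defaulting to 0.01 for polished-read
emulation (configurable; polished-read error rates are
platform-dependent and no canonical value exists).  Read length
responds to the indels actually inserted.  Base qualities are constant
placeholders.  Alternatively a target length distribution
(log-normal(μ=8.0, σ=0.6), ≈ 3 kb median, or an empirical length sample
permuted onto reads) replaces the decay model when no reference fit is
available.  Identical inputs and seed give byte-identical output.

Decay fitting uses sample L-moments l₁, l₂ (unbiased
probability-weighted moments from order statistics) and the two-branch
rational approximation of the gamma shape as a function of the L-CV
t = l₂/l₁ (branches split at t = 0.5; accuracy ~10⁻⁵ relative against
numerical inversion of τ(α) = Γ(α+½)/(√π Γ(α+1))), then β = l₁/α.
Observed shortenings are measured as transcript-coordinate distances
from read 5′ ends to the nearest upstream annotated TSS on compatible
transcripts; negative distances (reads extending beyond every TSS) are
excluded.  Fit input is truncated at 10,000 nt by default: the
empirical shortening distribution is heavy-tailed above that, which is
better explained by reads linked to the wrong (distant) annotated TSS
than by decay; pass `truncate_at=None` to disable.

## Toy reference generator

`make_toy_reference` builds a random genome with GT-AG introns
(plus-strand text CT…AC for minus-strand genes), genes of 4–8 exons
(120–400 nt) with 200–800 nt introns, and exon-skipping isoform
variants.  Every isoform keeps the transcript-5′-most exon and hence
its first junction, so no isoform's chain is a 5′-truncated suffix of a
sibling's — this makes decay-free simulations exactly recoverable and
is asserted by a generator test.  Rearrangement mode forces the two
partner genes onto `+`, plants a translocation with both breakpoints in
introns (so the novel fusion junction is GT-AG spliceable), flattens
the donor neighbourhood so the planted junction is the unique canonical
candidate within the refinement radius, and emits the breakpoint truth
table.  `perfect_read_records` converts a simulation truth table into
the records an ideal spliced aligner would produce; pipeline tests use
it to isolate the collapsing logic from aligner behavior.

What the fixtures do not emulate: alignment error and mapping
ambiguity, repeat-mediated mis-mapping, intron-less pseudogenes,
antisense transcription, biological TSS/TTS heterogeneity beyond decay,
chimera artifacts from library preparation.  Passing tests therefore
validate the algorithms' contracts, not robustness to aligner noise.

## Simulation designs and the DTU stand-in

Sweep design: every isoform at relative expression 1 except a uniformly
chosen 10% of (≥ 2-isoform) genes, where a uniformly chosen isoform
pair gets expression `fold_change` (default 4) in opposite groups;
non-DTU isoforms of DTU genes stay at 1.  Cohort-based design: baseline
(log-averaged) expression is permuted within the FSM and NIC strata
separately; ⌊0.04n⌋ genes are drawn first as DGE∩DTU, then each label
is topped up to ⌊0.25n⌋ / ⌊0.10n⌋ (the overlap constraint is stated in
the design; drawing the intersection first is our sampling mechanism);
DGE scales all isoforms of a gene by √f up in one group and down in the
other (ratio f, geometric mean — the log-average — preserved exactly);
DTU genes are visited in shuffled order and the pair type (two FSM /
FSM+NIC / two NIC) is chosen to keep the running NIC tally on the
proportional track to the target NIC rate, selecting the
highest-expression isoforms of the required categories; unattainable
rates raise an error listing the attainable range.  The realized NIC
share is within one pair of the target.

Counts: per sample, isoform counts are negative-binomial with mean
depth·p (p ∝ group expression × length) and variance μ + d·μ²
(d = dispersion; d = 0 gives Poisson).  The DTU test is a per-gene
multinomial likelihood-ratio test of isoform-proportion homogeneity
between groups on group-pooled counts (df = m−1), with per-isoform
isoform-vs-rest follow-up (df = 1) and stage-wise correction: BH across
gene p-values (screening), then BH across the isoform p-values of
screened genes (confirmation).  This engine is deliberately simple
plumbing for evaluating assemblies: it assumes multinomial sampling, so
overdispersed counts inflate gene-level calls, and in true DTU genes
the non-designated isoforms' proportions shift as a side effect and can
reach significance.  External DTU results can be imported as TSV and
scored with `evaluate_dtu` (precision and recall against the designated
isoform pairs) instead.

## Problem sizes

The test and acceptance runs use 50-gene toy references with up to 5
isoforms per gene, 3,000–5,000 reads per sample, 1,000–5,000 simulated
genes for the design metrics, Monte-Carlo gamma refits at n = 10⁵, and
the exhaustive Fisher sweep over all margins ≤ 30 — sizes chosen so the
full loop exercises every code path while remaining quick on one CPU.

## Known limitations

* No graph-based assembly or novel-junction discovery from noisy
  alignments: chains are taken from the alignments as given.
* The mapq and intron-size thresholds assume an upstream spliced
  aligner; PAF input requires a `cg` CIGAR tag for exon resolution.
* The DTU stand-in is not a replacement for dedicated engines (see
  above).
* Fusion analysis handles 2- and 3-segment chimeras only, and the
  external-breakpoint search for candidate double-hops is out of scope.
* The SQANTI-style artifact filter is rule-based; no classifier is
  trained.
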