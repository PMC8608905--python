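# isoforge

Multi-sample long-read transcriptome assembly and simulation toolkit.

Long-read (e.g. PacBio Iso-Seq) cDNA sequencing reads whole transcripts,
but the reads are redundant — RNA degrades from the 5′ end, so many
reads are 5′-truncated copies of the same isoform — and a single sample
rarely shows every isoform a cohort expresses.  `isoforge` builds a
cohort-wide transcriptome from per-sample spliced alignments, and ships
the simulation machinery needed to validate such assemblies.  It is a
library first (`import isoforge`, see `examples/`), with a thin
`isoforge` command-line wrapper.

## What it does

**Collapsing.**  Multi-exon reads merge when their ordered
splice-junction chains are identical; the merged isoform takes the most
upstream TSS and most downstream TTS of its supports (all original ends
retained).  Within a sample, an isoform whose junction chain is a
contiguous 3′-terminal run of a longer compatible isoform's chain (with
its span contained) is absorbed as a 5′-truncated fragment.  Across
samples, truncated survivors stay independent unless chains match
exactly — a chain observed intact in any sample is evidence of a real
exon–intron structure.  Mono-exon reads merge only with each other, by
same-strand overlap.  Per sample, an isoform is *detected* only by
non-truncated support, and its *PBcount* is the sum of full-length read
counts linked to it uniquely.

**Classification.**  Isoforms are categorized against a reference
annotation with the standard ladder — FSM, ISM, NIC, NNIC, plus
fusion / genic / genic-intron / antisense / intergenic — junction motifs
(GT-AG, GC-AG, AT-AC, non-canonical) are read from the genome, and
rule-based artifact labels (TP = full splice match; TN = carries a
junction that is both novel and non-canonical) feed the built-in filter.

**Cohort statistics.**  Detection matrices over two sample groups are
partitioned into common / unique / subtype-specific / other calls.  The
subtype test is an exact two-tailed Fisher test computed by integer
enumeration of hypergeometric point masses:
p = Σ { P(table) : P(table) ≤ P(observed) } over tables with the
observed margins.  Subtype-specific isoforms are ranked by
log₂((m₁+ε)/(m₂+ε)) of mean TPM, ε = 0.01, clipped to ±10.

**Fusion transcripts.**  Chimeric reads (2–3 aligned segments) define
fusion points with a few bp of uncertainty; if exactly one joint offset
within ±10 bp places a canonical donor–acceptor pair across the break,
the point is adopted as a spliced fusion point.  Points link to genomic
SV breakpoints within 100,000 bp (spliced) or 100 bp (exonic), both
sides inclusive; three-segment reads with both points linked are
double-hop fusion transcripts.  Fusion-specific junctions are junctions
absent from both the reference and the non-chimeric cohort.

**Simulation.**  Reads are drawn from transcripts with probability ∝
relative expression × length; a Gamma(α, β) number of bases is removed
from the 5′ end (the 3′ end is exact); per-base substitution /
insertion / deletion errors let read length vary.  The decay model is
fitted by L-moments (the `pelgam`-style rational approximation of the
shape from the L-CV t = l₂/l₁).  Experiment designs assign DTU (10% of
genes, isoform pairs boosted ×4 in opposite groups) and DGE (25%, with
4% overlap, ±√4 so log-average expression is preserved), steer the
FSM/NIC mix of DTU pairs to a target NIC rate, generate
negative-binomial counts, and score calls from the built-in multinomial
DTU test with stage-wise BH correction.

## Worked example

`examples/collapse_cohort.py` simulates two samples of 2,000 error-free
full-length reads from a 20-gene toy genome and collapses them:

```
annotated transcripts : 60
cohort isoforms       : 60
gene groups           : 20
detected in both      : 60
  PB.1.1: exons=5 pbcount={'s1': 52, 's2': 41}
  PB.1.2: exons=4 pbcount={'s1': 33, 's2': 31}
  PB.1.3: exons=3 pbcount={'s1': 19, 's2': 32}
```

With no decay and no error the cohort recovers exactly the 60 expressed
junction chains, grouped back into the 20 genes; PBcounts are the
per-sample unique full-length read counts.  `examples/fusion_transcripts.py`
refines a chimeric read whose raw fusion point is 3 bp off:

```
raw fusion point     : 2129 -> 35520
refined fusion point : 2126 -> 35517 (spliced=True, motif=GT-AG)
planted junction     : 2126 -> 35517
linked SV            : sv_gene001_gene006 (summed distance 462 bp, spliced window 100,000 bp)
```

The other examples cover classification, subtype specificity, decay
fitting and the DTU simulation loop; each prints a short interpretation
of its numbers.

## Command line

```bash
isoforge collapse   --sample-sheet sheet.tsv --alignments s1.bam --alignments s2.bam --out cohort.gtf
isoforge classify   --gtf cohort.gtf --ref annotation.gtf --genome genome.fa --out classes.tsv
isoforge specificity --detect detection.tsv --sheet sheet.tsv --out calls.tsv
isoforge fusion     --alignments s.bam --sv sv.tsv --ref annotation.gtf --genome genome.fa --out fusions.tsv
isoforge simulate   --transcripts t.fa --n 250000 --seed 1 --out reads.fastq --truth truth.tsv
isoforge fit-decay  --alignments s.bam --ref annotation.gtf
isoforge dtu        --counts counts.tsv --gene-map map.tsv --sheet sheet.tsv --out dtu
```

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
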