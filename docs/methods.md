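# Methods

`ribolite` re-creates, as a tested library, the computational path of a
ribosome-profiling (riboseq) + RNAseq study of cell-lysis artifacts: raw
reads are parsed into inserts and UMIs, cleaned of rRNA-like contaminants,
collapsed to unique molecules, aligned hierarchically to a tiered
transcriptome, counted fractionally per gene, quality-controlled, and tested
for differential expression and translation-efficiency change. A simulator
plants known effects so that every stage can be checked against ground
truth. This note documents the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Read anatomy and preprocessing

A raw riboseq read is modeled as

    <prefix, 3 nt> <insert, 28-30 nt> <UMI, 8 nt> <3' adapter AGATCGGAAGAGCACACGTCTGAA>

where the prefix consists of untemplated bases added during reverse
transcription (drawn from {C, G} in the simulator, reflecting the reverse
transcriptase's preference), the insert is the ribosome-protected fragment,
and the UMI tags the molecule before PCR. The parser:

1. locates the adapter by exact match of its first 12 nt, then allows at
   most one mismatch over the remaining overlap with the read. A 12-nt exact
   seed makes spurious matches vanishingly rare (4^-12) while one mismatch in
   the tail absorbs sequencing error; indel tolerance is unnecessary because
   the UMI sits at a fixed offset from the adapter;
2. takes the 8 nt immediately 5' of the adapter as the UMI and everything
   between the prefix and the UMI as the insert;
3. rejects reads with one of four enumerated reasons: `no_adapter`,
   `too_short` (insert < 20 nt), `too_long` (insert > 45 nt), or
   `ambiguous_base_in_umi` (an N would make the dedup key ambiguous).

Contaminant filtering precedes UMI collapsing: a read is discarded when its
insert aligns full-length to any contaminant-tier reference (rRNA, tRNA,
sno/snRNA stand-ins) within 3 mismatches. Collapsing then keeps the first
read per distinct (insert, UMI) pair. The key is deliberately
pre-alignment — sequence plus UMI — so deduplication does not depend on the
aligner; position-keyed collapsing would give identical results here because
identical inserts align identically.

RNAseq mates are only adapter-trimmed (the two library adapters are fixed
strings); there is no UMI step. The pipeline maps trimmed mate 1; at the
simulated fragment sizes mate 2 carries no extra information for
transcript-level counting.

## Alignment and counting

The aligner reports, for an insert of length L, every transcript offset at
which the full-length Hamming distance is at most `max_mismatches`
(default 3), forward strand only by default. Reads with more than
`max_loci` (default 100) placements are suppressed entirely, mirroring
bowtie's `-m` behavior; `seed_length` (default 25) is the minimum insert
length the aligner accepts. Candidate offsets come from pigeonhole seeding:
the insert is cut into `max_mismatches + 1` chunks and the leading k-mer of
each chunk (index k = 6) is looked up exactly; any placement within the
mismatch budget must contain at least one mismatch-free chunk, so the
procedure is exactly equivalent to a brute-force scan of every offset (the
test suite asserts this equivalence against an independent oracle). When a
read is too short for pigeonhole chunks of k nt the aligner falls back to
the full scan.

Alignment is hierarchical: coding-tier transcripts first; only reads with
zero reportable coding hits are tried against the non-coding tier. A read
suppressed at the coding tier also has zero reportable hits and is passed
on; in practice such reads are almost always ambiguous everywhere. No read
ever contributes to both tiers.

Counting distributes each mapped read over the k distinct genes among its
hits with weight 1/k — the unique weighting that assigns uniquely mapping
reads a count of 1 and conserves column totals (sum of a sample's gene
counts = number of mapped, non-suppressed reads, exactly). Transcript-level
counts use the same rule over distinct transcripts, for per-isoform
profiles.

## Riboseq quality control

All QC uses raw 5' ends with no P-site offset (a fixed offset parameter is
exposed but defaults to 0). The frame of an in-CDS 5' end is
`(position - cds_start) mod 3`; triplet periodicity is the weighted fraction
of ends per frame. Metagene profiles average transcript-normalized per-offset
densities (each transcript's profile divided by its own hit total, so deeply
covered transcripts do not dominate) around the first nucleotide of the
start or stop codon; offsets outside a transcript are excluded from the
average rather than zero-filled. Per-transcript coverage profiles are scaled
by a library-size factor defined as the sample's mapped-read total divided by
the geometric mean of all samples' totals — symmetric in any number of
samples, and equal to the pairwise ratio convention for two samples.
Multi-mapped hits contribute their fractional alignment weight throughout,
consistent with counting.

## Differential expression and the TE contrast

Counts are normalized with median-of-ratios size factors: the per-gene
reference is the geometric mean across samples (over genes positive in all
samples), the per-sample factor is the median ratio to that reference, and
factors are renormalized to geometric mean 1. This normalization assumes
most genes are not differentially expressed; planting a large one-sided
effect on a large fraction of genes biases it (composition bias), which is
why recovery simulations embed affected genes sparsely.

Per gene the model is negative binomial, `mu = s_j * q * 2^(beta * x_j)`
with `Var = mu + alpha * mu^2`, where `x_j` indicates condition B.
The per-condition abundances are method-of-moments estimates (means of
normalized counts), making the effect estimate an exact function of
normalized counts: rescaling one sample's column together with its size
factor cannot change any log2 fold change. The Wald standard error comes
from the NB Fisher information at the fitted means,
`Var(beta) = 1/sum_B W + 1/sum_A W`, `W = mu/(1 + alpha*mu)`.

Dispersion alpha is estimated per gene by within-condition method of
moments (pooled over conditions, Bessel-corrected), then shrunk linearly
toward a parametric trend `alpha(mu) = a0 + a1/mu` fit across genes by
least squares (weight 0.5 by default, exposed). Estimates are clipped to
[1e-8, 10]. This is a deliberately transparent stand-in for MAP shrinkage;
its accuracy is bounded by the calibration and recovery tests rather than by
asymptotic argument.

Because the dispersion is a plug-in estimate from few replicates, the raw
Wald statistic against the standard normal is slightly anticonservative at
the default 3+3 design. The Wald variance is therefore inflated by a
small-sample correction factor (default 1.1, exposed), calibrated on null
simulations at the default design so the empirical type-I error sits at the
nominal level. Genes with zero counts everywhere are flagged untestable and
reported with log2fc 0, p 1. P-values are two-sided and BH-adjusted within
each assay.

The translation-efficiency (TE) change is tested as the difference of the
two assays' effects, `delta = beta_ribo - beta_rna`, with
`se = sqrt(se_ribo^2 + se_rna^2)` under the assumption that the two assays
are independent libraries (true in this design; an interaction-GLM variant
would be the natural extension if shared samples were ever used).

Each gene then receives one of four regulatory classes from the three
BH-significance flags at level alpha (default 0.05):

| class | color | rule |
|---|---|---|
| transcription | blue | ribo and rna change, TE does not |
| translation | red | ribo changes alone, TE changes |
| buffering | pink | rna changes alone, TE changes |
| concordant | violet | ribo, rna and TE all change, same sign |

anything else is `none`. The "most enriched" gene-set filter uses strict
inequalities (fold change > threshold AND padj < threshold), with defaults
fold 4 and padj 1e-150 matching the convention for deeply sequenced data;
in-silico experiments use a practical reporting filter (fold > 2,
padj < 0.05) configured separately.

## Set statistics

Overlap enrichment reports `(overlap/|A|) / (|B|/|universe|)` plus the
upper-tail hypergeometric probability of an overlap at least as large
(equivalently the one-sided Fisher exact p of the 2x2 table; the test suite
asserts the equivalence exhaustively on small universes). The universe
defaults to genes passing the testability filter in both assays, a choice
exposed to the caller since no single universe is canonical. The
Mann-Whitney U test is exact when `n1*n2 <= 64` and the data are tie-free,
otherwise the normal approximation with midrank tie correction and
continuity correction; two identical constant samples are degenerate and
reported with p = 1. Term enrichment runs the same Fisher machinery per term
of a user-supplied term-to-gene annotation with BH across terms — it stands
in for an external GO service and deliberately ships no ontology.

## The simulator: what it emulates, and what it does not

The generator draws, per gene and sample, a negative-binomial template count
(`mean_expression` default 200 templates/gene/sample, `nb_dispersion`
default 0.05 — typical biological variability for cell-line replicates) and
applies the planted log2 fold change of the gene's class in the second
condition. Default classes: 40 `background` genes (0, 0); 8
`depleted_target` genes (riboseq +3.5, RNAseq +1.5) emulating
cytoskeleton-associated mRNAs recovered under gentle lysis, with a stronger
ribosome-footprint response so the true class is `concordant`; 8
`membrane_enriched` genes (-2, -2) emulating mitochondrial/ER-bound mRNAs
enriched under stringent lysis equally in both assays (`transcription`).
Effect sizes are set so each significance flag has high per-gene power at
3 replicates, mean 200 and dispersion 0.05 (Wald SE ~0.28 log2 units).

Riboseq reads place 5' ends uniformly over frame-0 CDS positions
(`frame0_prob`, default 1.0, sends the remainder to +1/+2 offsets), insert
lengths uniform in 28-30 nt, an 8-nt UMI, and the fixed adapter. PCR
duplicates are exact copies: each template emits `1 + Poisson(rate)` reads
(`pcr_duplication_rate` default 0.3 — the study this emulates does not
report its duplication rate, so the default is an unremarkable mid-range
value, exposed in config). Distinct templates are guaranteed distinct
(insert, UMI) keys — the generator resamples the UMI on the rare within-
sample collision — so UMI collapsing recovers template counts exactly, by
construction. A contaminant fraction (default 0.15) of inserts is drawn from
rRNA-like references. RNAseq samples get adapter-terminated paired fragments
(30-60 nt) without UMIs or duplication. Transcripts are random-sequence:
5' UTR (30-60 nt), ATG-initiated stop-terminated CDS of 100-150 codons free
of internal in-frame stops, 3' UTR (60-100 nt).

What the simulator does **not** model — and hence what passing tests do not
demonstrate about real data: sequencing errors (including UMI errors),
splicing and genome coordinates, multiple isoforms per gene (so real
multi-mapping rates are far higher), biased nuclease digestion and true
P-site offsets, GC/length biases, and library-composition effects beyond the
planted classes. The recovery results are therefore statements about the
pipeline's correctness under its own model, not about biological
sensitivity.

## Problem sizes and numerical conventions

Default in-silico experiments use 56 genes x 2 assays x 2 conditions x 3
replicates (~170k riboseq reads per experiment), sizes at which a full run
takes seconds to tens of seconds on one core while leaving per-gene counts
(~200) in the regime the differential machinery targets. Ties in UMI
collapse and multi-hit ordering are broken by input order; alignment hits
are sorted by (transcript, position); all randomness flows from a single
integer seed through named per-stage generators, making every output file
byte-reproducible. Manifests record SHA-256 hashes of all outputs plus the
config snapshot; the fingerprint excludes the timestamp so reproducibility
is checkable.

## Known limitations

* The aligner is exhaustive and in-memory; it is built for simulated-scale
  references (tens of kilobases), not a full transcriptome.
* Dispersion moderation is moment-based with a two-parameter trend; genes
  with extreme dispersion profiles are handled by clipping rather than
  outlier refitting (no Cook's-distance analogue).
* The TE test assumes assay independence; paired designs would need the
  interaction-GLM extension.
* `buffering` and `translation` classes are exercised by the classifier's
  unit tests but not by the default experiment templates, whose planted
  classes are `none`/`concordant`/`transcription`.
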