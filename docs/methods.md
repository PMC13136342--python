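# Methods

This note documents the models, conventions and numerical choices behind
`tdrprof`, and what the synthetic-data tests do and do not demonstrate
about real sequencing data.

## Reference model

All coordinates are 0-based half-open internally; 1-based GFF coordinates
are converted only at the I/O boundary. Mature tRNA sequences are consumed
pre-spliced from FASTA; tRNA introns are never spliced from genomic
coordinates. The post-transcriptional 3′ CCA is appended to every mature
model by default (configurable via the bundle manifest), because 3′ tDRs
carry CCA in vivo and would otherwise fail to align within the model. The
anticodon offset is taken from the annotation when present
(`anticodon_start=` on the FASTA header); otherwise the occurrence of the
anticodon 3-mer closest to the canonical offset 34 is used, with an exact
distance tie going to the 5′-most occurrence.

## Sequential classification

Class priority follows the processing order rRNA → miRNA → tRNA → piRNA,
then genome. A read belongs to the first class in which it has at least one
best-stratum alignment (best stratum = minimal mismatch count; default
`max_mismatch=0` for synthetic fixtures, 1 is recommended when ingesting
real alignments). Multi-mapping within a class splits the read into
fractional weights 1/n over the tied features, which keeps class totals and
percentages exactly conserved — the suite asserts
`sum(class totals) + unassigned == input reads` to machine precision.

Genome-stage reads overlapping a transcript are mRNA fragments when the
alignment strand equals the transcript strand and endo-siRNAs otherwise;
genome hits outside any transcript stay `genome_only` and count toward the
total-genome denominator but neither transcript class. External SAM/BAM
alignments are ingested per stage with the same priority semantics; mismatch
counts are taken from the NM tag as-is.

The internal exhaustive aligner exists for hermetic fixtures: exact matches
use C-level substring search on both strands, and the Hamming-distance path
(mismatches ≥ 1) is a plain scan intended only for small references.

## tDR metrics

The mature tRNA is split at the anticodon: 5′ arm `[0, anticodon_start)`,
3′ arm `[anticodon_start+3, L)`; the three anticodon positions belong to
neither arm. A read is assigned to the arm containing the majority of its
aligned positions, with an exact tie going to 5′ — chosen because anticodon-
loop cleavage makes the 5′ half the dominant species of interest, and the
rule is deterministic. Whether the original analyses assigned spanning reads
by read start or by overlap is not documented anywhere we could rely on;
majority overlap is this package's documented choice. Antisense tRNA
alignments never enter arm fractions; they are tallied separately.

The tRNA-half boundary is **30 nt binned as "short"** (long means
strictly >30 nt). The boundary is a parameter (`threshold`) everywhere it
appears. Isoacceptor rollups sum isodecoder depth vectors 5′-anchored,
padding shorter models with zeros at the 3′ end, since tDR positions are
defined from the mature 5′ end.

## Normalization

`rpm = count / denominator × 10⁶` with the denominator explicit in every
report header: `total_genome`, `genome_minus_rRNA`, or `class:<name>`.
The rRNA-excluded denominator exists because an expanded rRNA degradation
background compresses rpm values of every other class under total-genome
normalization; making the denominator a visible, stamped choice avoids that
artifact silently shaping comparisons. Switching denominators rescales all
features of a sample by one common factor (rank-preserving), which the
suite checks.

## Statistical battery

* **Mann–Whitney U** (two-sided): exact permutation null when there are no
  ties and n₁+n₂ ≤ 12, otherwise the tie-corrected normal approximation
  with continuity correction. Ties always force the asymptotic path because
  exact enumeration under ties has no canonical convention. The exact path
  is verified against brute-force enumeration of every rank split for all
  configurations with combined n ≤ 10.
* **BH adjustment** is applied within one family per call; in pipeline
  reports a family is one panel's set of tests (all classes of one
  comparison, or all length bins of one comparison).
* **Welch's t** and the pooled-variance t return p = 1 when both groups are
  constant and equal, p = 0 (flagged degenerate) when both are constant but
  different.
* **Coverage-profile comparison** treats positions along the mature tRNA as
  observations in a Welch's t on depth vectors, optionally rescaled to
  reads per million by library size. This is a deliberate, documented
  construction: positions are not independent, so the p-values are
  heuristic enrichment scores that respond strongly to global abundance
  shifts, not calibrated error rates. The exact observational unit used in
  comparable published analyses is typically unstated; this package does
  not claim to reproduce any particular published p-value from this test.
* **KS two-sample** uses the asymptotic null; **log-rank** is the standard
  1-df chi-square via lifelines, with Kaplan–Meier curves available from
  the same table.

Type-I calibration is checked by simulation at α = 0.05 over 1,000
replicates: Welch's t at n = 50 per group, and log-rank at n = 100 per arm
with 10% censoring — the regime where its asymptotic chi-square
approximation is accurate. A known limitation: with ~50 subjects per arm
the log-rank test is mildly anti-conservative (empirically ≈ 6% at nominal
5% under exponential survival with light censoring).

## Single-embryo differential expression

TPM is computed as `(count/length) / Σ(count/length) × 10⁶` per sample;
columns of a TPM matrix must sum to 10⁶ within 10⁻³ relative tolerance
(filtering genes afterwards intentionally breaks the sum but keeps the
scale, tracked by the `TPM(filtered)` unit tag). The expression filter
default is mean TPM ≥ 1 in at least one condition — a standard detection
rule, recorded verbatim in the output metadata and fully tunable.

The DE rule is |log₂FC| > 1 and p ≤ 0.01 from an unpaired two-tailed
t-test on per-embryo TPM. Fold changes use a pseudocount of 1 TPM
(configurable) because single embryos contain genuine zeros. Tests default
to the TPM scale with a `log_transform` flag for log₂(TPM+ε); no multiple-
testing correction is applied by default since the rule operates on raw p,
with BH available as an option. Gene groups resolve by locus-name stem
(the part before the first hyphen, so "hsp" matches *hsp-16.2* but not
*hsph-1*) or by curated list — canonical histones are a curated list
because *C. elegans* histone loci are named *his-N* and H3.3 variants must
be excluded. Group regulation is read from the ECDF of member log₂ fold
changes versus all remaining genes (two-sample KS + median shift), which
detects coordinated sub-threshold shifts that per-gene calls miss.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and defines its working conditions:

* **Class mixtures.** Sperm-like libraries plant 13.8% tRNA reads, male-like
  libraries 3.3%, inside realistic mixtures dominated by endo-siRNAs,
  miRNAs and mRNA fragments. The mutant condition multiplies the tRNA class
  weight by 2.5 (matching an 8.6% vs 3.5% contrast) and moves 60% of tDR
  mass into 31–36 nt 5′ halves.
* **tDR structure.** tDRs are emitted as 5′-anchored prefixes or 3′-anchored
  suffixes of mature (CCA-bearing) tRNAs with configurable arm bias
  (default 52% 5′ for males, 42% for sperm) and length distribution
  (baseline concentrated below 30 nt).
* **Backgrounds.** rRNA fragments start uniformly with geometrically
  short-skewed lengths, giving the uniform first-nucleotide, small-fragment
  signature of degradation. Endo-siRNAs are exact 22 nt antisense G-start
  reads against configured loci; piRNAs are 21 nt U-start.
* **Embryo matrices** are negative binomial with lognormal per-gene
  baselines (four orders of magnitude of expression), default dispersion
  0.05 and 10–15 embryos per condition; planted effects are per-gene or
  per-group log₂ shifts. **Survival** is exponential with independent
  exponential censoring.

The miniature reference bundle (6 mature tRNAs including Gly-GCC, Glu-CTC
and Ser-AGA isodecoders, 2 rRNA stubs, 5 miRNAs, 3 piRNAs, 4 transcripts in
a toy genome) is generated deterministically from a fixed internal seed and
verified to be mutually unique at the 18-mer level including reverse
complements — which is what makes 100% classification recovery achievable
and meaningful as a correctness oracle.

Deliberately not simulated: sequencing errors, RNA modifications and
ligation bias, multi-mapping between references, intron-containing tRNAs,
and fragment-level mRNA simulation for the embryo arm. Passing tests
therefore demonstrate correctness of the analysis logic under unambiguous
references, not robustness to aligner noise or cloning artifacts in real
libraries; on real data the classifier consumes external SAM/BAM alignments
and inherits their error model.

## Problem sizes

The verification suite uses 50,000 reads for classification recovery,
100,000 for class-fraction consistency, 10,000 tDRs for arm assignment,
1,000 replicates for each type-I simulation and oracle comparison, and
2,000–5,000-gene matrices for DE recovery and null false-positive rates —
sizes at which binomial/multinomial tolerances (3 SDs) are tight enough to
be informative while the whole suite runs in about a minute.

## Known limitations

* The toy aligner is exhaustive and unsuitable beyond fixture-scale
  references; real libraries should arrive as SAM/BAM.
* The coverage-profile Welch test is an enrichment heuristic (positions are
  correlated observations), as discussed above.
* Transcript overlap takes the first overlapping gene; overlapping gene
  models are not resolved further.
* rpm/TPM conventions assume single-end small-RNA reads and gene-level
  quantities; no UMI handling, batch correction or imputation.
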