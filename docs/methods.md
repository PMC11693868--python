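# Methods

`ribosel` analyses paired transcriptome/translatome profiling: for each of two
conditions (A and B) a cytosolic RNA library and a ribosome-associated RNA
library are quantified at transcript level, and the package asks, at
increasing resolution, (i) which genes differ in expression or translation
between conditions, (ii) which genes differ in translational efficiency, and
(iii) within each condition, which genes' isoform composition the ribosome
reshapes — and which mRNA structural elements distinguish the preferred from
the avoided isoform.

## Data model

Transcript models are held with 0-based half-open genomic intervals; GTF I/O
converts from the format's 1-based inclusive convention. UTRs are derived, not
read: the non-coding exonic intervals upstream of the CDS in transcript
orientation form the 5'UTR, those downstream the 3'UTR, so for every coding
transcript |5'UTR| + |CDS| + |3'UTR| equals the exonic length exactly.
Non-coding transcripts are kept and flagged; their element decomposition is
undefined and structural comparison against a coding partner reports every
element present in either.

Quantification enters as a single merged TSV (counts and FPKM per transcript
per library). Transcripts present in the catalog but absent from the table are
treated as zero, matching assembler behaviour of dropping unexpressed
isoforms. Gene-level values are exact sums over the gene's transcripts.

## Differential expression and translation

With one library per condition within a fraction there are no replicates, so
the per-gene test is a Fisher exact test on the 2×2 table of (gene count,
library remainder) across the two libraries — the only exact count-based test
available without a dispersion estimate. Benjamini–Hochberg adjustment runs
over the expression-filtered family (FPKM ≥ 1 in at least one condition), and
a gene is called only when all three criteria hold: |log2 FC| ≥ 1, the
expression filter, and adjusted P ≤ 0.001. The fold change uses a 0.25-FPKM
pseudocount; the test never does. All thresholds are configuration.

This framework models *technical sampling* of a fixed mRNA pool. It is exact
under multinomial sampling and anti-conservative under biological
overdispersion — with per-gene variance m + φm², the score statistic inflates
by roughly 1 + φm. That is a property of any replicate-free design, not of
this implementation; see *Limitations*.

## Translational efficiency

TE is the gene-level ratio of ribosome-associated to cytosolic FPKM within a
condition, defined where cytosolic FPKM ≥ 1. The two conditions' TE vectors
are restricted to their common eligible genes and normalized to [0, 1] before
comparison. The default normalization is the empirical quantile (rank)
transform, (rank − 1)/(n − 1) with average ranks for ties: abundance ratios
are heavy-tailed, and under min–max scaling a single outlier compresses every
other gene into a band narrower than any usable threshold. Min–max remains
available (`te_norm: minmax`). A gene is differentially translated when the
normalized TEs differ by more than 0.5. Note the rank transform makes the
0.5 threshold a statement about quantile displacement, not about the raw
ratio; a gene must overtake half the family to be called.

## Selective isoform usage

Within one condition, an isoform's composition proportion (CP) is its share of
the gene's counts in one fraction, computed over isoforms passing a
per-transcript FPKM ≥ 1 filter in that fraction and renormalized. CP uses
estimated counts, not FPKM: within-gene proportions cancel length only when
isoform lengths are equal, and count proportions are what the contingency test
below consumes. Genes with ≥ 2 expressed isoforms in the union of fractions
are testable.

The test is a Pearson chi-square on the 2×k table (cytosolic counts over
ribosome counts), with two small-sample modifications, both configurable and
both off-able: a per-cell pseudocount (default 0.5) and merging of
low-expectation bins — while any expected cell is below 5 and more than two
bins remain, the two lowest-usage bins merge into an "other" bin, with df =
k′ − 1 on the merged table. With both modifications off the statistic is the
textbook Pearson chi-square, which is what the oracle tests assert against an
independent Σ(O−E)²/E implementation. BH q-values are computed across the
testable family; q ≤ 0.05 defines selective usage.

Per isoform, Diff_CP = CP_ribo − CP_cyto over the union isoform set (absent
isoforms carry CP 0), so Σ Diff_CP = 0 per gene. The maximally positively and
negatively selected isoforms are the argmax/argmin of Diff_CP, ties broken by
higher cytosolic CP then lexicographic id. For that extreme pair the package
reports the set of structural elements — 5'UTR, 3'UTR, CDS — whose genomic
interval sets differ (after interval normalization).

The dominant transcript of a gene in one fraction is the top-CP isoform when
it holds CP ≥ 0.5 *and* at least twice the runner-up's CP (single-isoform
genes are dominant by definition); both constants are configuration, as a
concrete operationalization of "considerably higher" expression. A gene's
dominant status between fractions is `unchanged`, `switched`, or `undefined`
when either fraction lacks a rule-dominant isoform.

A two-sample proportion test (chi-square with Yates continuity correction,
the classic prop-test convention) compares the fraction of genes using ≥ 2
isoforms between transcriptome and translatome.

## Synthetic data generator

The generator is first-class, tested code and the ground-truth source for all
recovery statistics. Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | genes on one pseudo-chromosome |
| `isoform_count_weights` | (.45,.30,.15,.07,.03) | 1–5 isoforms/gene, mean ≈ 1.9 |
| `mean_expression_log2`, `sd_expression_log2` | 5.0, 1.5 | log-normal baseline abundance |
| `te_log2_sd` | 1.0 | per-gene baseline TE spread, shared between conditions |
| `nb_dispersion` | 1e-6 | NB dispersion; near-Poisson technical sampling |
| `frac_de_genes`, `de_log2fc` | 0.1, 2.0 | condition-B expression shifts, random sign |
| `frac_te_shift_genes`, `te_shift_log2` | 0.1, 3.0 | condition-B ribosome-fraction shifts |
| `frac_selection_genes`, `selection_cp_shift` | 0.1, 0.3 | CP mass moved onto one isoform in the ribosome fraction |
| `frac_dominant_switch` | 0.1 | top-two CP swap in the ribosome fraction |
| `library_depth` | 2×10⁶ | expected reads per library |

Isoforms of a gene share a CDS core and differ from the base isoform in 5'UTR
start, 3'UTR end, or CDS stop position, each isoform with a distinct offset,
so any two isoforms differ exactly in the union of their planted element sets
— giving the structural comparison known answers. Moving a stop codon
necessarily changes the 3'UTR too (UTRs are exon − CDS), so the CDS variant's
truth is {cds, utr3}. Cytosolic isoform proportions are Dirichlet(α = 2);
selection moves `selection_cp_shift` of CP mass onto the highest-CP isoform
that can absorb it; a switch swaps the two largest proportions (applied after
the shift, so the planted argmax always moves). Counts are negative binomial
around depth-scaled expectations; FPKM uses realized library sizes. A
`noise_seed` argument redraws only the count noise, holding planted effects
fixed, for Monte-Carlo checks.

The dispersion default deserves emphasis: 1e-6 emulates the sampling noise of
sequencing a fixed pool, which is the regime in which the replicate-free
Fisher/chi-square framework is calibrated (and the regime the generator's
null model is meant to represent). The generator happily produces
overdispersed data (`nb_dispersion=0.1`), and doing so demonstrates the
framework's anti-conservatism — it does not make the callers wrong so much as
it makes the replicate-free design unable to separate biology from noise.

What the generator does *not* emulate: positional ribosome occupancy, UTR
sequence content (only interval structure), correlated effect layers between
DE/TE/selection (draws are independent Bernoulli, overlaps recorded), and
library-preparation biases. Passing recovery tests therefore shows the
statistical machinery is correct and calibrated under the stated sampling
model, not that real libraries meet that model.

## Numerical choices

- Fisher exact via `scipy.stats.fisher_exact` (two-sided minimum-likelihood
  convention); validated against a gammaln tail enumeration to 1e-12.
- Chi-square via `scipy.stats.chi2_contingency(correction=False)` on the
  (possibly pseudocounted/merged) table; validated to 1e-9 against Σ(O−E)²/E.
- Counts are rounded to integers for the Fisher table (quantified "estimated
  reads" are real-valued); the chi-square consumes them unrounded.
- Rank normalization of a single value maps to 0.5; min–max of a constant
  vector maps everything to 0.5 with a warning.
- Degenerate proportion-test tables (a zero success or failure column) return
  p = 1.
- All tie-breaks (extreme isoforms, dominant calls, table sorting) are
  deterministic; result TSVs are written sorted with floats at 6 significant
  digits, and a MANIFEST of SHA-256 checksums makes byte-level reproducibility
  checkable.

## Limitations

- No replicate-aware inference (DESeq2-style NB GLMs are an explicit
  non-goal); with biological replicates those methods should be preferred and
  this framework's p-values read as descriptive.
- The differential-TE rule is a threshold on normalized TE difference, not a
  significance test; its operating characteristics depend on the normalization
  (rank by default) and the family composition.
- Structural comparison is interval-level only: isoforms differing in sequence
  but not in intervals (impossible from one catalog) or in uORF/IRES content
  are out of scope.
- The chi-square modifications (pseudocount, merging) are one reasonable
  operationalization of small-sample robustness; both are recorded in output
  metadata and can be disabled.
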