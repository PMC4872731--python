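# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Somatic calling from tumor/normal allele counts

At a tested site with tumor counts (t_alt, t_ref) and normal counts
(n_alt, n_ref), the latent allele fractions get independent conjugate
posteriors under uniform Beta(1,1) priors:

    p_T ~ Beta(t_alt + 1, t_ref + 1)
    p_N ~ Beta(n_alt + 1, n_ref + 1)

The test statistic is the one-sided posterior probability
P(p_T > p_N).  Because read counts make the shape parameters integers,
the probability is evaluated with the exact finite-series form of the
beta exceedance probability (a sum of t_alt + 1 log-beta terms) rather
than numerical quadrature; the test suite validates it against a
10^6-draw Monte-Carlo oracle on a 20-case grid and against the analytic
value 5/6 for the single-read case Beta(2,1) vs Beta(1,2).  Symmetric
inputs short-circuit to exactly 0.5.

Calling uses two gates, both configurable: `p_threshold = 0.99` on the
posterior probability and `max_normal_vaf = 0.03` on the observed normal
VAF.  The second gate exists because the posterior comparison alone
cannot distinguish a somatic event from a germline heterozygote with a
tumor-side allelic imbalance; 3% tolerates sequencing error and minor
contamination without admitting heterozygotes.  The defaults give a
measured false-positive rate well under 2% at depth 100 on null
simulations, with ≥ 95% sensitivity at purity 0.8.

Consequence annotation is rule-based on a single-transcript model:
indels in the CDS are one class (not split frameshift/in-frame), SNVs
within 2 intronic bases of an internal exon boundary are splice-site,
CDS SNVs are translated through the spliced frame (minus strands on the
reverse complement; codons spanning exon junctions are assembled from
the spliced sequence), and everything else in the span is noncoding.
The reference codon is taken from the transcript sequence, so the
classification is always self-consistent with the model.

The substitution spectrum collapses the 12 raw SNV types onto 6 classes
by mapping purine references to their pyrimidine complements.  Gene
recurrence counts a gene once per sample and only for protein-altering
classes (missense, nonsense, stop-loss, splice-site, indel).

## Gene-level copy number

Inputs are exon-level log2 ratios with an upstream significance flag
(exon-capture callers provide one; whole-genome segments are rasterized
onto exons first, each exon taking the log2 of its dominant-overlap
segment and significance meaning |log2| beyond a cutoff).  Per gene:

- significant-exon fraction < `min_fraction` (default 0.2) → neutral;
- otherwise the **median** log2 of the significant exons decides:
  > `gain_cut` (0.3) → gain, < `loss_cut` (−0.3) → loss;
- a non-decisive median with significant exons on both sides → mixed.

The median was chosen as the gene-level summary because it is order-free
and robust to a single discordant exon; `affected_exons` lists the
significant exons consistent with the assigned state.  Intragenic
deletion detection reports significantly lost exons only when they form
a non-empty strict subset of the gene (whole-gene loss is not
intragenic) — this is the one-of-three-exons VHL-type event.

Cohort percentages round half-up to integers (5/9 → 56%, 6/9 → 67%).
Cross-platform concordance is the percentage of (sample, gene) keys with
exactly matching states; rasterization onto a shared gene model defines
the common key space.  Arm-level calls require segments beyond a cutoff
to cover ≥ 50% of the arm's length — a pragmatic choice, exposed as a
parameter.

## Fusion consensus

The two callers are combined by **union**, not intersection: a pair
reported by one caller survives with its tool provenance recorded.  The
merge key is the ordered (5′ gene, 3′ gene) pair; breakpoints are kept
as annotations, not keys, because caller-reported breakpoints for the
same event routinely differ by a few bases and no principled tolerance
is available.  Support counts are per-pair maxima.  The support filter
requires ≥ 2 spanning pairs AND ≥ 1 junction-spanning read (both
configurable).

A consensus record is a read-through when both genes are on the same
chromosome and strand, the 3′ partner is the *nearest* downstream
same-strand gene of the 5′ partner in its transcription direction, and
the intergenic gap is ≤ 200 kb.  The gap cap and the nearest-neighbour
requirement encode what read-throughs are — transcription running past
a terminator into the adjacent gene — while excluding distant same-strand
rearrangements.

Recurrence counts a pair once per sample; private means exactly one
sample.  Partner overexpression flags a gene whose RPKM in the fusion's
sample is ≥ 2× its cohort mean.  The interchromosomal table counts
non-read-through fusions per unordered chromosome pair (Circos-style).

## Expression

RPKM = counts × 10⁹ / (library size × gene length in bp).

The outlier-sum (OS) statistic standardizes a gene's vector with the
median and the MAD (no consistency constant; at MAD = 0 the scale falls
back to IQR/1.349, and a fully degenerate vector scores 0), flags
samples whose standardized value exceeds q75 + IQR (linear-interpolation
quantiles), and sums the flagged values.  The one-group variant is used
— the cohort has no normal-tissue expression arm.  The pipeline default
applies OS to log2(RPKM + 1), the scale on which expression noise is
roughly symmetric.

**Small-cohort behaviour.**  The q75 + IQR fence is affine-invariant, so
the fraction of genes with at least one flagged sample depends only on
the sample count and noise shape, not on scale.  At n = 9 this fence is
permissive: on null log-normal matrices roughly a third of genes flag
some sample.  OS is therefore used as a *ranking* statistic — planted
8× outliers rank in the top decile in ≥ 90% of replicates — and a
non-zero OS alone should not be read as significance at this cohort
size.

Fold-change DE between groups uses fc = (mean_a + c)/(mean_b + c) with
pseudocount c = 0.1 guarding zeros, selecting fc ≥ 2 or ≤ 0.5.  This is
deliberately the simple filter; negative-binomial testing is out of
scope.  Outlier–CNA integration intersects, per gene, the OS outlier
samples with the samples carrying a gain call for that gene.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) for an n-gene query
overlapping a K-gene set by k inside an N-gene universe, each set
intersected with the universe first; BH step-up q-values across sets.
The default universe is all genes of the analyzed model.  A plain
hypergeometric tail was chosen over modified Fisher variants whose
exact universes are tied to external services.  Note that enlarging the
universe with genes outside query and sets can only *decrease* the
tail p — the overlap becomes rarer under the null.

## Synthetic cohort

The generators emulate the statistical structure each stage consumes,
with a per-base error rate of 0.001 and Poisson depths throughout:

- **Sites**: somatic sites have tumor VAF purity/2 (one mutant copy,
  diploid, diluted by normal cells) and error-rate normal VAF; germline
  hets 0.5/0.5; reference error/error.  Counts are binomial at
  Poisson(depth) coverage.
- **Exon CNA**: unaffected exons ~ N(0, σ), event exons ~
  N(±effect, σ) and flagged significant; single-exon losses are planted
  in 3–5-exon genes so one lost exon still clears the 20% fraction.
- **Fusions**: each true (sample, pair) record is detected independently
  per caller (defaults 0.9 and 0.8) with support drawn above the filter
  thresholds; false positives draw random pairs with support
  deliberately below them.  Planted read-throughs are adjacent
  same-strand neighbours from the synthetic model.
- **Expression**: per-gene log-normal baselines, multiplicative
  log-normal noise (σ = 0.3 natural-log), Poisson sampling; outlier
  genes ×8 in a 2-of-9 sample subset; group-effect genes ×2^effect in
  labelled samples.  Library sizes are the realized column sums.

The default cohort layout mirrors the nine-sample design of the shipped
clinical table (two gastric wild-type, three gastric KIT-mutant, four
small-intestinal), so group summaries exercise the same strata.

What the generators do **not** emulate: mapping artifacts and strand
bias, GC- and mappability-dependent coverage waves, subclonal
heterogeneity and copy-number-driven VAF shifts, correlated exon noise
within segments, breakpoint-sequence effects on fusion detectability,
and gene–gene expression correlation.  Passing recovery tests therefore
demonstrates correctness of the integration logic under the stated
noise models, not caller performance on real sequencing data.

## Problem sizes and numerical notes

Calibration tests use 10⁴ null sites, 2×10³-site sensitivity replicates
over 5 seeds, 20-replicate CNA and outlier recovery studies, a 10⁶-draw
Monte-Carlo oracle on a 20-case grid, and exhaustive enumeration of the
hypergeometric tail for every universe size ≤ 12 — sizes at which every
check completes in seconds while leaving binomial error well inside the
asserted margins.  Posterior probabilities are computed in log space
(scipy `betaln`) and clipped to [0, 1]; quantiles use numpy's
linear-interpolation convention throughout; percentage rounding is
half-up (never banker's).  Degenerate inputs are contract errors, not
silent results: zero depth, empty exon blocks, overlapping DE groups,
sub-4-sample OS vectors and empty universes all raise typed exceptions.

## Known limitations

Single transcript per gene (no isoform-aware consequence calls);
multi-allelic sites are skipped on VCF ingestion; no purity/ploidy
correction of copy number; fusion identity ignores breakpoints, so two
distinct events between the same partners in one sample merge; the OS
fence is permissive at n = 9 (see above); the command-line `report` is a
convenience summary, not an analysis artifact.
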