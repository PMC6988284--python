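# Methods

This note documents the models, conventions and design choices behind
`cnvpop`, in the spirit of a software methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and coordinates

The pipeline consumes per-sample CNV calls (PennCNV-style rawcnv text),
per-sample array QC metrics, a per-SNP × per-sample log-R-ratio (LRR)
matrix, phased or unphased SNP genotypes, gene models (GFF3) and QTL
positions. It does not call CNVs from raw intensities: the HMM caller,
GC-wave adjustment and intensity normalisation are upstream of this
package, and the synthetic generator stands in for them. All internal
coordinates are 1-based inclusive (the convention of rawcnv and GFF3);
BED output is converted to 0-based half-open at the I/O boundary only.
Only autosomes are modelled.

## Sample QC and call merging

Samples are removed when any signal metric strictly exceeds its threshold
(LRR SD > 0.30, BAF SD > 0.001, waviness factor > 0.05 — the caller's
default criteria; boundary values pass). Call-level outliers are removed
by a deterministic two-part rule: more than 100 calls per sample, or total
called length above Q3 + 3·IQR of the per-sample totals. The length rule
replaces visual QQ-plot inspection with an explicit criterion so that runs
are reproducible; both cut-offs are configurable. Split calls are re-joined
when two same-sample, same-chromosome, same-CN-state neighbours have
gap/(merged span) < 0.10, where gap = start₂ − end₁ − 1 and merged span =
end₂ − start₁ + 1. Merging is applied left-to-right and iterated to a
fixed point, because a rightward merge can widen a span enough to enable a
merge with an earlier neighbour; the procedure is idempotent (property
tested). "Total length" is read as the span of the would-be merged call,
the interpretation of the caller's companion cleaning script; the
alternative (sum of member lengths) is a one-line change in the gap test.

## CNVR construction and genotyping

Regions are the transitive closure of ≥ 1 bp overlap across all samples
(bookended calls, start₂ = end₁ + 1, never join). The span is the union of
members, so CNVR spans are pairwise disjoint per chromosome and genome
coverage is the plain sum of region lengths. Typing: deletion iff all
member states < 2, duplication iff all > 2, complex otherwise. Bi-allelic
(non-complex) regions are genotyped from member calls: deletion CN 1 → one
alternate allele, CN 0 → two; duplication CN 3 → one, CN 4 → two; samples
without a member call are reference homozygotes. A sample with several
member calls takes its most extreme state; CN ≥ 5 (rare in array data) is
clamped to dosage 2 with a warning, since the bi-allelic model cannot
represent more than two alternate alleles. A call that only partially
overlaps the union span still makes its sample a carrier — this is implied
by the union definition and means allele frequencies are frequencies of
*any* overlapping event. MAF classes: common ≥ 0.05, intermediate
[0.01, 0.05), rare < 0.01. (Printed sources for this kind of analysis are
inconsistent about the upper intermediate bound, 0.05 vs 0.1; 0.05 is used
throughout because it is the complement of the common class.) Site
frequency spectra use left-closed 0.05-wide bins on [0, 0.5], last bin
closed.

## Functional categories

Each CNVR receives exactly one label. A region is intergenic when it
touches no gene body and no promoter window. Otherwise the priority is:
whole_gene (≥ 1 gene fully contained), stop_codon (overlap with any
transcript's stop-codon span; when the annotation has no explicit
stop_codon feature the last coding codon on the coding strand is used),
promoter (strand-aware [TSS−500, TSS−1] on +, [TSS+1, TSS+500] on −),
intronic (every gene-body overlap avoids all exons of the genes involved),
and exonic as the residual genic class. Promoter-only overlap counts as
genic. The ordering of the lower classes (promoter before intronic) is a
choice; it matters only for regions that touch a promoter of one gene and
an intron of another.

The overlap-enrichment test re-places every region uniformly at random,
preserving length — chromosome drawn with probability proportional to its
number of valid start positions, start uniform among them, no masking —
1000 times by default. The statistic is the count of regions overlapping
≥ 1 feature by ≥ 1 bp; both the z-score (obs − mean)/sd and the empirical
p = (#{perm ≥ obs} + 1)/(n_perm + 1) are reported, the latter because it is
well defined when the permutation distribution is tight. A degenerate scan
(permutation SD = 0, e.g. features covering the whole genome) reports z as
NaN rather than failing. Category-association tests are plain Pearson
chi-square without continuity correction, with a warning when expected
cells fall below 5.

## Fst

The per-locus estimator is Weir & Cockerham (1984) in its allele-count
(one-way ANOVA) form: with alt-allele counts and totals per population,
θ̂ = (MSP − MSG)/(MSP + (n_c − 1)·MSG), where MSP and MSG are the
among-/within-population mean squares of the allele indicator and n_c the
variance-corrected mean sample size. This form takes only allele counts —
the natural unit for CNVR dosages — and satisfies θ̂ = 1 at a fixed
difference and E[θ̂] ≤ 0 under the null; slightly negative estimates are
reported as-is, never clamped. Loci monomorphic in both populations are
undefined and reported missing, which is why the number of loci with an
Fst value can be smaller than the number of bi-allelic regions. The
outlier scan flags loci strictly above mean + 3·SD (SD with ddof = 1) of
the defined values.

## Vst

For a region, each sample is summarised by its unweighted mean LRR over
the SNPs inside the span (the summarisation is not standardised in the
literature; the unweighted mean is the simplest choice). Then
Vst = (V_T − (V₁n₁ + V₂n₂)/(n₁ + n₂))/V_T with denominator-n variances.
With population variances the law of total variance guarantees
Vst ∈ [0, 1]; with ddof = 1 the bound can break at small n, which is why
denominator-n is the default. V_T = 0 is degenerate and reported as
Vst = 0. The minimum-copy filter removes regions with fewer than 5
supporting calls in either (or, in `both` mode, in each of) the two
populations; "copies" counts member calls, not carrier samples (the two
differ for homozygous carriers; configurable upstream by the caller).

## LD and taggability

Variants entering LD analysis are filtered on MAF < 0.001, call rate
< 90 % (SNPs only — CNVR genotypes derive from calls, not array clustering,
so the criterion does not apply), and exact Hardy–Weinberg p < 1e−9. The
HWE test enumerates the conditional heterozygote-count distribution by
recurrence; the suite checks it against an independent closed-form
enumeration for n ≤ 200. SNPs positioned inside any CNVR span (inclusive)
are masked to avoid signal-driven artefacts. r² is computed from
haplotypes as D²/(p_A q_A p_B q_B) when truth phase is available, else as
the squared Pearson correlation of dosages (composite LD); the mode is
recorded per pair. CNVR–SNP distance is measured from the SNP to the
nearest region boundary. Decay profiles report the mean r² per 10 kb bin
within 100 kb, with empty bins as missing, and the SNP–SNP reference set
is restricted to the MAF range of the common CNVRs being profiled.
Taggability is the maximum r² over SNP partners within the window;
variants without a partner are undefined, not zero. QTLs are matched to
partner SNPs by position (nearest r²-bearing SNP within 10 kb), because
QTL records carry no marker identity here.

## The synthetic cohort

The generator emulates a two-breed dairy-cattle BeadChip cohort. Defaults
(all configurable) are the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_pop1 / n_pop2 | 315 / 107 | post-QC analysis sets of the mirrored study |
| genome | 5 × 20 Mb autosomes | desk-scale stand-in for 2.49 Gb over 29 autosomes |
| SNP spacing | exp., mean 3.4 kb | ≈ 295 SNPs/Mb, HD-array density |
| n_cnv_loci | 200 | ~38 expected calls/sample (inside the 30–55 band) |
| deletion_fraction | 0.64 | 1.8 : 1 deletion : duplication calls in expectation |
| locus lengths | exp., mean 44.2 / 74.6 kb | deletions shorter than duplications |
| CNV allele freq | Beta(0.6, 6), clipped [0.002, 0.45] | rare-skewed spectrum |
| n_diverged_loci / Δaf | 5 / 0.4 | planted differentiation targets |
| LRR shifts | CN0 −2.0, CN1 −0.5, CN3 +0.3, CN4 +0.6 | typical array separation |
| lrr_noise_sd | 0.16 | good-quality sample noise |
| fp_singleton_rate | 2 calls/sample | illustrative false-positive load |
| boundary_jitter_sd | 2 kb | sub-resolution breakpoint error |

Haplotypes follow a latent Gaussian AR(1): z at each SNP is the previous z
scaled by exp(−d/L) (L = 60 kb) plus orthogonal noise, thresholded at each
SNP's target frequency. This is a first-order Markov model that preserves
per-SNP frequencies exactly while giving SNP–SNP r² that decays with
distance (property tested). Each CNV locus is anchored to a SNP just
outside its span: within each population, haplotypes carrying the anchor
allele are preferentially made carriers so that true CNV–SNP LD exists,
with carrier probabilities adjusted so the expected frequency matches the
target even when the anchor frequency is smaller. A quarter of duplication
loci (configurable) ignore the anchor ("dispersed" duplications), emulating
duplications that land on a different haplotype background and therefore
tag poorly. Deletion CN ∈ {0,1,2} and duplication CN ∈ {2,3,4} per sample
follow from the two haploid CNV alleles. Calls are emitted per carried
locus with Gaussian boundary jitter, plus Poisson false-positive singleton
calls placed uniformly outside the true loci. BAF is represented only by a
per-sample BAF-SD QC metric; no allelic intensity model is attempted.

What the generator does **not** emulate — and what passing tests therefore
do not show about real arrays: GC-content waves and other long-range
intensity artefacts, probe-density heterogeneity (segmental-duplication
deserts), genuine gene/CNV co-location biases (genes and CNV loci are
placed independently, so the permutation test is expected to be null on
synthetic data), linked SNP allele-frequency divergence between the
populations (SNPs are drawn from a shared frequency spectrum; only the
planted CNV loci are diverged), and multi-allelic or mosaic copy states.

Because the genome is scaled down ~25× while per-sample call counts are
kept at study levels, genome-wide CNVR coverage on synthetic data is
correspondingly inflated (tens of percent rather than single digits);
coverage arithmetic itself is exercised separately on published counts in
the acceptance suite. Likewise the LRR signal here is clean and strongly
shifted, so the Fst–Vst concordance is high even before minimum-copy
filtering; the filter's effect is asserted as a direction (filtered >
unfiltered), not as the magnitude seen on real data.

## Numerical conventions

All randomness flows from a single integer seed through named
`numpy.random.Generator` streams, so outputs are byte-identical across
runs. SD uses ddof = 1 wherever a threshold is derived from data (outlier
scans) and ddof = 0 where a variance decomposition requires it (Vst).
Strict inequalities are used exactly where the mirrored procedures state
them: QC removal, the 10 % merge rule, the mean + 3 SD scan, minimum-copy
(< 5) and the 0.8 tagging threshold. Undefined quantities (monomorphic
Fst/r², empty LD bins, partnerless taggability) are reported as missing
and excluded from aggregates, never coerced to 0. Problem sizes in tests
and the acceptance script (small cohorts for unit tests, the 315 + 107
default cohort for end-to-end checks, 10 000 permutations for the
enumerable calibration toy) were chosen to keep full runs in the order of
seconds to a few minutes on one CPU.
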