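# Methods

This note documents the statistical procedures `rohpop` implements, the
conventions it pins where the field admits more than one choice, what the
synthetic-data generator does and does not emulate, and known limitations.

## Genotype model and QC

Genotypes are diploid biallelic SNP calls coded 0/1/2 as copies of the ALT
allele, missing as a sentinel; positions are 1-based internally and every
BED export is 0-based half-open. QC applies four filters in a fixed order —
individual call rate ≥ 0.90, site call rate ≥ 0.90, MAF ≥ 0.05 (from
non-missing alleles only), Hardy–Weinberg exact-test p ≥ 1e-6 — because the
order changes the result and must be pinned; this order mirrors common
PLINK practice. The HWE test is the conditional exact test (two-sided tail
of configurations no more probable than the observed heterozygote count,
no mid-p), pooled across populations by default with a per-population
option; pooling is the natural default when differentiation is weak, which
is exactly the regime the island analysis targets.

## Diversity

H_O is the heterozygote fraction among non-missing calls per site; H_E =
2p̂q̂ without small-sample correction (the 2n/(2n−1) correction is behind a
flag — both are standard and the uncorrected form is the common default).
Windowed π sums per-site π = 2·c_ref·c_alt/(n(n−1)) over a window and
divides by the full window length in bp, SNP-free gaps included, matching
the convention of the widely used windowed-π tools; windows are half-open
[start, start+window) tiles starting at position 1, and SNP-free windows
report 0.

## Structure

PCA mean-imputes missing dosages per site, centres by 2p̂ and scales by
√(2p̂q̂) (monomorphic sites dropped), and eigendecomposes the sample
covariance; variance shares are eigenvalue shares, and component signs are
fixed deterministically. LD r² is the squared Pearson correlation of
genotype dosages over co-called samples (composite LD) — the only option
for unphased data; pairs monomorphic in the co-called subset are skipped.
Pruning follows the 50-SNP/5-step/r² > 0.5 sliding-window rule, removing
the later site of each offending pair in lexicographic order, which makes
the retained set a fixed point. Neighbor joining is the canonical Q-matrix
algorithm with smallest-(i, j) tie-breaking and negative branch lengths
clamped to zero with a warning; on additive distances it provably recovers
the generating topology, which the tests exploit. F_ST is the
Weir–Cockerham (1984) estimator; the genome-wide value is the ratio of
summed variance components, never a mean of per-site ratios.

## ROH detection

The caller is the SNP-count sliding-window procedure: windows of 50
consecutive SNPs are homozygous-eligible when they contain at most 1
heterozygous and 1 missing call; each SNP's score is the eligible fraction
of the *realised* windows overlapping it (so chromosome ends need no
padding); SNPs with score ≥ 0.05 that are not themselves heterozygous are
candidates (a heterozygous SNP can never bridge two runs); maximal
candidate stretches are cut where consecutive candidates lie more than
100 kb apart; a stretch becomes a segment from its first to last SNP and
is kept iff length ≥ 50 kb, density ≥ 1 SNP/50 kb and SNP count ≥ the
minimum-SNP filter. The score threshold 0.05 is read as the SNP-inclusion
proportion of the sliding-window method; this is documented prominently
because the parameter's plain-language description is ambiguous.

The minimum SNP count defaults to the Lencz value
⌈ln(α/(n_s·n_i)) / ln(1−h̄)⌉ with α = 0.05, n_s the SNP count, n_i the
individual count and h̄ the mean observed heterozygosity of the data (an
explicit override is available). At a cohort scale of 6,588,886 SNPs, 146
individuals and h̄ = 0.254 this gives 81. Segment lengths use 1-based
inclusive coordinates (end − start + 1); length classes are
(0, 0.1], (0.1, 0.2], (0.2, 0.4], (0.4, 0.8], (0.8, 1.6], (1.6, ∞) Mb with
boundary values in the lower class. Per-chromosome coverage is reported as
summed ROH length / (chromosome length × number of individuals), i.e. the
mean per-individual fraction; density counts segment midpoints per 1 Mb.

## Inbreeding coefficients

F_ROH = Σ segment lengths / Σ chromosome lengths per individual.
F_HOM = (C_obs − C_exp)/(N − C_exp), where N is the individual's
non-missing genotype count and C_exp sums 1 − 2p̂q̂·2n/(2n−1) over the same
sites (cohort allele frequencies, small-sample-corrected). The
denominator choice follows the method-of-moments statistic of the standard
`--het`-style implementations; interpreting N as the cohort size instead
would not yield a coefficient bounded by 1, so that reading is rejected.
F_HOM may be negative (excess heterozygosity).

## ROH islands and the selection contrast

Per-SNP occurrence is the fraction of individuals whose ROHs span the SNP;
SNPs strictly above 0.50 are high-frequency. Merged intervals (gap ≤
100 kb, the same gap rule as detection) are a reporting convenience over
the per-SNP definition — no merge rule is canonical. Hp uses
genotype-derived major/minor allele counts in place of pooled read counts:
the statistic's original definition is read-based, but this package
consumes genotypes, and the substitution preserves the form and the
[0, 0.5] bounds; values are therefore comparable only within an analysis,
not against read-based Hp from other pipelines. π and Hp at island scale
use 40 kb windows with a 20 kb step; Tajima's D uses non-overlapping 40 kb
windows with the canonical constants (a₁…e₂) at n = twice the modal
co-called diploid count of the window, and is undefined (not zero) when
S = 0 or n < 4. Windows are classified island > roh > non-roh by interval
overlap, and group differences are tested with two-sided Mann–Whitney U —
a rank test is appropriate because the window statistics are strongly
non-normal; empty groups skip the comparison with a warning. Gene mapping
is plain interval intersection against GFF3 `gene` features (malformed
lines skipped with a count), reporting per-gene member-SNP counts.

## Synthetic-data generator

The simulator emulates the statistical structure of a weakly
differentiated wild cohort: ancestral allele frequencies uniform on
[maf_floor, 1 − maf_floor] (default floor 0.05), population frequencies
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) at F = fst_target (F = 0
short-circuits to copying p), genotypes from inbreeding-adjusted
Hardy–Weinberg probabilities, SNP positions from uniform draws at a target
mean spacing (sorted, deduplicated — irregular spacing deliberately
stresses the density and gap rules), uniform missingness, and planted
homozygous intervals whose alleles are drawn by population frequency.
Planted intervals are strictly homozygous and exempt from missingness:
realism (genotyping error inside true IBD) is traded for exact
testability. One seed governs all draws in a documented order, so fixtures
are byte-reproducible. Defaults (4 populations × 36 individuals, ~300 bp
spacing, F_ST ≈ 0.01, ≤10% missingness) mirror a multi-site
resequencing cohort; with a uniform frequency prior the per-site
heterozygosity is ≈ 0.36, somewhat above a typical wild cohort's 0.25 —
raising maf_floor lowers it if desired.

What the generator does *not* emulate: linkage disequilibrium and
recombination (sites are independent given frequencies), demographic
history, selection, sequencing error, and allele-frequency spectra shaped
by mutation models. Passing recovery tests therefore demonstrate
correctness of the estimators under their own sampling assumptions, not
robustness to LD or demography on real data.

## Test and verification conditions

The end-to-end checks run at scales chosen to give stable statistics while
keeping the suite quick: planted-ROH recovery uses 20 individuals on one
5 Mb chromosome at ~300 bp spacing with 30 planted ROHs of 0.2–1.0 Mb
(recall ≥ 0.95 with boundaries within one 50-SNP window span, and
per-carrier F_ROH within ±10% of the planted fraction); F_HOM recovery
uses 200 individuals × ~50,000 SNPs at planted F = 0.10; F_ST recovery
uses two populations of 100 at F_ST = 0.1 over ~10,000 SNPs for three
seeds; the island contrast uses 30 individuals sharing one fixed
homozygous haplotype over 0.5 Mb of an 8 Mb chromosome (~400 windows).
Every windowed or per-site statistic is checked against an independent
oracle (full enumeration for the HWE exact test; brute-force allele-pair
counting for π; step-by-step constant recomputation for Tajima's D;
per-site tallies for IBS; direct Pearson correlation for r²; brute-force
interval merging for islands) at tolerances of 1e-10 to 1e-12, and NJ is
checked against 100 random additive 8-taxon trees and cross-checked
against an independent implementation.

## Known limitations

- The ROH caller assumes reasonably dense, well-spaced SNPs; chromosomes
  with fewer SNPs than one window are skipped with a warning.
- Hp is a genotype-based proxy for the read-based statistic (above).
- LD decay on very dense data is quadratic in SNPs within the distance
  cap; use pruned or thinned input for genome-scale decay curves.
- Island intervals depend on the occurrence threshold (strict > 0.50);
  thresholds in the literature vary widely, so interval lists are best
  treated as candidates, not calls.
- No phasing, imputation, multiallelic handling, admixture inference or
  demographic reconstruction; these are out of scope.
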