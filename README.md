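# rohpop

Runs-of-homozygosity (ROH), inbreeding and diversity analysis for
whole-genome-resequencing SNP genotypes of diploid organisms.

`rohpop` is aimed at population geneticists working with wild or farmed
cohorts — e.g. aquaculture species sampled from several locations — who want
to go from a filtered multi-sample VCF to: per-population diversity tables,
population-structure summaries, per-individual ROH calls and genomic
inbreeding coefficients, and candidate selective-sweep regions ("ROH
islands") with their overlapping genes. A bundled synthetic-genotype
simulator with known ground truth (planted ROHs, known F_ST and inbreeding)
backs every stage with parameter-recovery tests.

## What it computes

**QC** (PLINK-style, fixed order: individual call rate → site call rate →
MAF → Hardy–Weinberg exact test), then:

- **Diversity**: MAF spectra, observed/expected heterozygosity
  (H_O, H_E = 2p̂q̂), windowed nucleotide diversity
  π = Σ_sites 2·c_ref·c_alt / (n(n−1)) per bp of window.
- **Structure**: allele-frequency-standardised PCA; identity-by-state
  distance (1 − IBS) with a deterministic neighbor-joining tree; LD r²
  (genotype-dosage correlation), LD decay curves and PLINK-style pruning;
  Weir–Cockerham (1984) F_ST as the ratio of summed variance components.
- **ROH detection**: the sliding-window method — 50-SNP windows
  classified homozygous-eligible (≤1 het, ≤1 missing), per-SNP eligibility
  score ≥ 0.05, runs cut at gaps > 100 kb and kept when length ≥ 50 kb,
  density ≥ 1 SNP/50 kb and SNP count ≥ the **Lencz minimum**
  l = ln(α / (n_s·n_i)) / ln(1 − h̄), the count that bounds at level α the
  genome-wide chance of a homozygous run arising without identity by
  descent.
- **Inbreeding**: F_ROH = ΣL_ROH / L_genome and
  F_HOM = (C_obs − C_exp) / (N − C_exp) with small-sample-corrected
  expected homozygosity.
- **ROH islands**: SNPs lying inside an ROH in > 50% of individuals,
  merged into intervals; pooled heterozygosity
  Hp = 2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)², Tajima's D and π in 40 kb
  windows; Mann–Whitney contrasts of island vs ROH vs non-ROH windows;
  GFF3 gene overlap for candidate-gene tables.

## Worked example

Simulate a two-population cohort (one 3 Mb chromosome, ~300 bp SNP
spacing, 5% missingness) with a 0.6 Mb ROH planted in two individuals,
then run QC, detection and the inbreeding coefficients:

```python
import rohpop as rp
from rohpop.synthio import genome_info

cfg = rp.SimulationConfig(
    n_populations=2, n_individuals_per_pop=15, n_chromosomes=1,
    chrom_length_bp=3_000_000, snp_spacing_bp=300, fst_target=0.01,
    missing_rate=0.05,
    planted_rohs=[(0, "chr1", 1_000_001, 1_600_000),
                  (1, "chr1", 1_000_001, 1_600_000)],
    seed=42,
)
matrix, truth = rp.simulate(cfg)
filtered, report = rp.apply_qc(matrix)
segments, min_snps = rp.detect_all(filtered)
froh = rp.f_roh(segments, genome_info(cfg), filtered.sample_ids)
```

Output (printing the calls and coefficients):

```
sites kept: 9159 of 9985
Lencz min SNPs: 35
P1_I000 chr1 1000058 1599753 1893 0.600 Mb 0.4-0.8
P1_I001 chr1  998567 1600076 1897 0.602 Mb 0.4-0.8
F_ROH carrier: 0.1999  truth: 0.2
mean F_HOM: 0.0192
H_O: 0.365 H_E: 0.365
```

The two planted runs are recovered with boundary errors of a few hundred
bp (well under one 50-SNP window span); the carrier's F_ROH matches the
planted genome fraction (0.6 Mb / 3 Mb = 0.2); H_O ≈ H_E confirms the
outbred background, and the small positive mean F_HOM reflects the two
planted segments.

The same pipeline runs from a shell:

```bash
rohpop simulate --config sim.yaml --seed 42 --out sim/
rohpop run --config run.yaml --out results/   # filter → … → report
rohpop roh --vcf cohort.vcf --popmap pops.tsv --out roh_out/
```

Each run writes TSV/BED artifacts per stage plus a `manifest.json` with
input checksums and the parameters used; identical inputs and config
reproduce identical bytes.

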