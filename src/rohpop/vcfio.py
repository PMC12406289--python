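"""VCF input/output and genotype quality control.

Reading uses cyvcf2; only biallelic SNP records are kept (others are skipped
and counted). Half-calls and ``./.`` become the missing sentinel. The QC
stage applies the standard resequencing filters in a fixed, logged order:
individual call rate -> site call rate -> minor allele frequency ->
Hardy–Weinberg exact-test p-value. The order is pinned because it changes
the result; it mirrors common PLINK practice.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, EmptyResultError, GenotypeMatrix, read_population_map

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    population_map: Mapping[str, str] | str | Path | None = None,
    allow_unmapped: bool = False,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged). Samples
    absent from ``population_map`` raise unless ``allow_unmapped`` is set,
    in which case they are labelled ``UNKNOWN``.
    """
    if population_map is not None and not isinstance(population_map, Mapping):
        population_map = read_population_map(population_map)

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in VCF header")
    if population_map is None:
        pops = ["UNKNOWN"] * len(sample_ids)
    else:
        missing = [s for s in sample_ids if s not in population_map]
        if missing and not allow_unmapped:
            raise ValueError(f"samples missing from population map: {missing}")
        pops = [population_map.get(s, "UNKNOWN") for s in sample_ids]

    rows: list[np.ndarray] = []
    site_rows: list[tuple] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1), allele -1 = missing
        a = gts[:, 0].astype(np.int16)
        b = gts[:, 1].astype(np.int16)
        code = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        rows.append(code)
        site_rows.append((str(var.CHROM), int(var.POS), var.REF, var.ALT[0],
                          var.ID or "."))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise EmptyResultError(f"no biallelic SNP records in {path}")

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt", "id"])
    geno = np.vstack(rows).T  # samples x sites
    order = np.lexsort((sites["pos"].to_numpy(),
                        pd.factorize(sites["chrom"], sort=False)[0]))
    if not np.array_equal(order, np.arange(len(sites))):
        warnings.warn("input VCF records were not sorted; sorting by (chrom, pos)")
        sites = sites.iloc[order]
        geno = geno[:, order]
    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops})
    return GenotypeMatrix(geno, sites, samples)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a VCF 4.2 file with GT-only FORMAT, one ALT per record."""
    lut = np.array([_GT_STRINGS[MISSING], _GT_STRINGS[0], _GT_STRINGS[1], _GT_STRINGS[2]])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohpop\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(matrix.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        chroms = matrix.sites["chrom"].to_numpy()
        poss = matrix.sites["pos"].to_numpy()
        refs = matrix.sites["ref"].to_numpy()
        alts = matrix.sites["alt"].to_numpy()
        ids = matrix.sites["id"].to_numpy()
        gt_str = lut[matrix.genotypes + 1]  # shift so MISSING -> index 0
        for j in range(matrix.n_sites):
            fh.write(f"{chroms[j]}\t{poss[j]}\t{ids[j]}\t{refs[j]}\t{alts[j]}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gt_str[:, j]) + "\n")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy–Weinberg exact-test p-value for one biallelic site.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) whose probability does not exceed
    that of the observed configuration. Monomorphic sites return 1 by
    convention. No mid-p correction is applied.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    # heterozygote counts sharing the parity of the rare-allele count
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hs) // 2
    hom_common = n - hs - hom_rare
    valid = hom_common >= 0
    hs, hom_rare, hom_common = hs[valid], hom_rare[valid], hom_common[valid]
    logw = (hs * math.log(2.0)
            - _lgamma_arr(hom_rare + 1)
            - _lgamma_arr(hs + 1)
            - _lgamma_arr(hom_common + 1))
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[np.flatnonzero(hs == n_het)[0]]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    return np.array([math.lgamma(float(v)) for v in x])


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-criterion removal counts, in application order."""

    thresholds: dict[str, float]
    steps: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (criterion, axis, n_removed, n_retained)

    def add(self, criterion: str, axis: str, removed: int, retained: int) -> None:
        self.steps.append((criterion, axis, removed, retained))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps,
                          columns=["criterion", "axis", "n_removed", "n_retained"])
        df["threshold"] = [self.thresholds.get(c, np.nan) for c in df["criterion"]]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def site_maf(matrix: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Minor allele frequency per site from non-missing alleles only."""
    ref, alt = matrix.allele_counts(sample_idx)
    tot = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.minimum(f_alt, 1.0 - f_alt)


def site_hwe_p(matrix: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    g = matrix.genotypes if sample_idx is None else matrix.genotypes[sample_idx]
    n_hom_ref = (g == 0).sum(axis=0)
    n_het = (g == 1).sum(axis=0)
    n_hom_alt = (g == 2).sum(axis=0)
    return np.array([
        hwe_exact_test(int(a), int(b), int(c))
        for a, b, c in zip(n_hom_ref, n_het, n_hom_alt)
    ])


def apply_qc(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    site_call_min: float = 0.90,
    ind_call_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    hwe_per_population: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the four QC filters in the fixed order.

    Order: individual call rate -> site call rate -> MAF -> HWE p-value.
    Every threshold is retained-if->=. The HWE test pools all samples by
    default; ``hwe_per_population`` instead requires every population's
    p-value to pass.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise EmptyResultError("empty genotype matrix")
    report = FilterReport(thresholds={
        "individual_call_rate": ind_call_min,
        "site_call_rate": site_call_min,
        "maf": maf_min,
        "hwe_p": hwe_p_min,
    })
    called = matrix.genotypes != MISSING

    ind_rate = called.mean(axis=1)
    keep_ind = ind_rate >= ind_call_min
    report.add("individual_call_rate", "samples",
               int((~keep_ind).sum()), int(keep_ind.sum()))
    if not keep_ind.any():
        raise EmptyResultError("individual call-rate filter removed all samples")
    m = matrix.subset_samples(keep_ind)

    site_rate = (m.genotypes != MISSING).mean(axis=0)
    keep = site_rate >= site_call_min
    report.add("site_call_rate", "sites", int((~keep).sum()), int(keep.sum()))
    if not keep.any():
        raise EmptyResultError("site call-rate filter removed all sites")
    m = m.subset_sites(keep)

    maf = site_maf(m)
    keep = np.nan_to_num(maf, nan=-1.0) >= maf_min
    report.add("maf", "sites", int((~keep).sum()), int(keep.sum()))
    if not keep.any():
        raise EmptyResultError("MAF filter removed all sites")
    m = m.subset_sites(keep)

    if hwe_per_population:
        keep = np.ones(m.n_sites, dtype=bool)
        for pop in m.populations:
            keep &= site_hwe_p(m, m.pop_indices(pop)) >= hwe_p_min
    else:
        keep = site_hwe_p(m) >= hwe_p_min
    report.add("hwe_p", "sites", int((~keep).sum()), int(keep.sum()))
    if not keep.any():
        raise EmptyResultError("HWE filter removed all sites")
    m = m.subset_sites(keep)

    for crit, axis, removed, retained in report.steps:
        logger.info("QC %s (%s): removed %d, retained %d", crit, axis, removed, retained)
    return m, report
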