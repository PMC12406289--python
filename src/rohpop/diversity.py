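"""Per-population diversity statistics: MAF spectra, heterozygosity, windowed pi.

Conventions pinned here: expected heterozygosity is 2*p*q without
small-sample correction (the corrected variant is available behind a flag);
window pi divides by the full window length in bp including SNP-free gaps;
windows are half-open [start, start + window) tiles starting at position 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenomeInfo, GenotypeMatrix
from .vcfio import site_maf


@dataclass
class DiversitySummary:
    """One row of a Table-1-style per-population summary."""

    population: str
    n_samples: int
    n_snp: dict[float, int]
    pn: dict[float, float]
    h_obs: float
    h_exp: float
    mean_pi: float

    def to_row(self) -> dict:
        row: dict = {"population": self.population, "n_samples": self.n_samples}
        for thr in sorted(self.n_snp):
            row[f"nsnp_{thr:g}"] = self.n_snp[thr]
            row[f"pn_{thr:g}"] = self.pn[thr]
        row.update(h_obs=self.h_obs, h_exp=self.h_exp, pi=self.mean_pi)
        return row


def maf_counts(
    matrix: GenotypeMatrix,
    population: str | None = None,
    thresholds: Sequence[float] = (0.05, 0.2),
) -> tuple[dict[float, int], dict[float, float]]:
    """Count sites with within-population MAF >= each threshold.

    Returns (counts, ratios); ratio = count / total retained SNPs.
    """
    idx = None if population is None else matrix.pop_indices(population)
    maf = site_maf(matrix, idx)
    counts = {float(t): int(np.nansum(maf >= t)) for t in thresholds}
    total = matrix.n_sites
    ratios = {t: c / total for t, c in counts.items()}
    return counts, ratios


def heterozygosity(
    matrix: GenotypeMatrix,
    population: str | None = None,
    unbiased: bool = False,
) -> tuple[float, float]:
    """(H_O, H_E) for a population: unweighted means across sites.

    Per site H_O is the heterozygote fraction among non-missing individuals
    and H_E = 2*p*q from the same calls; sites with zero calls are excluded
    from both means. ``unbiased`` applies the 2n/(2n-1) small-sample factor
    to H_E.
    """
    idx = None if population is None else matrix.pop_indices(population)
    g = matrix.genotypes if idx is None else matrix.genotypes[idx]
    called = g != MISSING
    n_called = called.sum(axis=0)
    ok = n_called > 0
    het = ((g == 1) & called).sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_o = np.where(ok, het / np.maximum(n_called, 1), np.nan)
        p_hat = alt / np.maximum(2 * n_called, 1)
        h_e = 2.0 * p_hat * (1.0 - p_hat)
        if unbiased:
            h_e *= 2 * n_called / np.maximum(2 * n_called - 1, 1)
    return float(np.mean(h_o[ok])), float(np.mean(h_e[ok]))


def site_pi(matrix: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Per-site nucleotide diversity 2*c_ref*c_alt / (n*(n-1)) over called alleles."""
    ref, alt = matrix.allele_counts(sample_idx)
    n = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n > 1, 2.0 * ref * alt / (np.maximum(n, 2) * (np.maximum(n, 2) - 1.0)), 0.0)
    return pi


def window_starts(span_end: int, window: int, step: int) -> np.ndarray:
    """Half-open window tiling [start, start+window), starts 1, 1+step, ..."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    return np.arange(1, span_end + 1, step, dtype=np.int64)


def windowed_pi(
    matrix: GenotypeMatrix,
    window: int = 20_000,
    step: int = 10_000,
    population: str | None = None,
    genome: GenomeInfo | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp of window length.

    Window pi = sum of per-site pi over SNPs in the window, divided by the
    window length in bp (SNP-free gaps included); SNP-free windows report 0.
    """
    idx = None if population is None else matrix.pop_indices(population)
    pi_sites = site_pi(matrix, idx)
    pos_all = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom, sl in matrix.chrom_ranges().items():
        pos = pos_all[sl]
        pi = pi_sites[sl]
        cum = np.concatenate([[0.0], np.cumsum(pi)])
        span_end = genome.lengths[chrom] if genome is not None else int(pos[-1])
        for start in window_starts(span_end, window, step):
            end = start + window  # half-open
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            rows.append((chrom, int(start), int(end - 1), int(hi - lo),
                         (cum[hi] - cum[lo]) / window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


def diversity_summary(
    matrix: GenotypeMatrix,
    thresholds: Sequence[float] = (0.05, 0.2),
    pi_window: int = 20_000,
    pi_step: int = 10_000,
    genome: GenomeInfo | None = None,
    include_all: bool = True,
) -> pd.DataFrame:
    """Table-1-style summary: one row per population plus a pooled ALL row."""
    pops = list(matrix.populations)
    groups: list[str | None] = list(pops)
    if include_all:
        groups.append(None)
    rows = []
    for pop in groups:
        label = pop if pop is not None else "ALL"
        n = len(matrix.pop_indices(pop)) if pop is not None else matrix.n_samples
        counts, ratios = maf_counts(matrix, pop, thresholds)
        h_o, h_e = heterozygosity(matrix, pop)
        wpi = windowed_pi(matrix, pi_window, pi_step, pop, genome)
        summary = DiversitySummary(label, n, counts, ratios, h_o, h_e,
                                   float(wpi["pi"].mean()))
        rows.append(summary.to_row())
    return pd.DataFrame(rows)
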