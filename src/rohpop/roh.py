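"""Sliding-window detection of runs of homozygosity (ROH).

The caller follows the classic SNP-based sliding-window procedure: windows
of a fixed SNP count are classified homozygous-eligible when they contain
at most a small number of heterozygous and missing calls; each SNP is
scored by the fraction of eligible windows among the windows that overlap
it (only realised windows count, so chromosome ends are handled); SNPs
whose score passes the threshold — and which are not themselves
heterozygous — become candidates; maximal candidate stretches are cut at
large physical gaps and kept only if they satisfy the minimum length,
minimum SNP count and minimum density filters.

The minimum SNP count defaults to the value of the Lencz formula, which
bounds at level alpha the genome-wide chance of a homozygous stretch
arising without identity by descent.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    LENGTH_CLASS_LABELS,
    MISSING,
    GenomeInfo,
    GenotypeMatrix,
    ROHSegment,
)


@dataclass(frozen=True)
class ROHParams:
    """Parameters of the sliding-window ROH caller.

    Defaults are the conventional whole-genome-resequencing settings:
    50-SNP windows, window-score threshold 0.05, at most one heterozygous
    and one missing call per window, minimum run length 50 kb, minimum
    density 1 SNP / 50 kb, maximum gap between consecutive run SNPs 100 kb.
    ``min_snps=None`` means: compute it from the data with the Lencz
    formula at alpha = 0.05.
    """

    window_snps: int = 50
    min_prop_homozygous_windows: float = 0.05
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    min_length_bp: int = 50_000
    min_density_snp_per_bp: float = 1.0 / 50_000
    max_gap_bp: int = 100_000
    min_snps: int | None = None

    def __post_init__(self) -> None:
        if self.window_snps <= 0 or self.min_length_bp <= 0 or self.max_gap_bp <= 0:
            raise ValueError("window, length and gap parameters must be positive")
        if not 0.0 < self.min_prop_homozygous_windows <= 1.0:
            raise ValueError("min_prop_homozygous_windows must be in (0, 1]")


@dataclass(frozen=True)
class LenczParams:
    """Inputs of the Lencz minimum-SNP formula."""

    alpha: float = 0.05
    n_snps: int = 1
    n_individuals: int = 1
    het_mean: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.het_mean < 1.0:
            raise ValueError("het_mean must be in (0, 1)")
        if self.n_snps < 1 or self.n_individuals < 1:
            raise ValueError("counts must be >= 1")


def lencz_min_snps(p: LenczParams) -> int:
    """Smallest integer >= ln(alpha / (n_s * n_i)) / ln(1 - het_mean)."""
    l = math.log(p.alpha / (p.n_snps * p.n_individuals)) / math.log(1.0 - p.het_mean)
    return max(0, math.ceil(l))


def mean_observed_het(matrix: GenotypeMatrix) -> float:
    """Fraction of heterozygous calls among all non-missing genotypes."""
    called = matrix.genotypes != MISSING
    n_called = called.sum()
    if n_called == 0:
        raise ValueError("no called genotypes")
    return float((matrix.genotypes == 1).sum() / n_called)


def resolve_min_snps(matrix: GenotypeMatrix, params: ROHParams,
                     alpha: float = 0.05) -> int:
    """The effective minimum-SNP filter: explicit override or Lencz value."""
    if params.min_snps is not None:
        return params.min_snps
    lp = LenczParams(alpha=alpha, n_snps=matrix.n_sites,
                     n_individuals=matrix.n_samples,
                     het_mean=mean_observed_het(matrix))
    return lencz_min_snps(lp)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_roh(
    matrix: GenotypeMatrix,
    sample_id: str,
    params: ROHParams = ROHParams(),
    min_snps: int | None = None,
) -> list[ROHSegment]:
    """Detect ROH segments for one individual.

    ``min_snps`` overrides the resolved minimum-SNP filter (pass the value
    from :func:`resolve_min_snps` when calling per sample in a loop, to
    avoid recomputing it).
    """
    if min_snps is None:
        min_snps = resolve_min_snps(matrix, params)
    row = matrix.genotypes[matrix.sample_index(sample_id)]
    pos_all = matrix.sites["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for chrom, sl in matrix.chrom_ranges().items():
        g = row[sl]
        pos = pos_all[sl]
        segments.extend(
            _detect_chrom(g, pos, chrom, sample_id, params, min_snps)
        )
    return segments


def _detect_chrom(
    g: np.ndarray, pos: np.ndarray, chrom: str, sample_id: str,
    params: ROHParams, min_snps: int,
) -> list[ROHSegment]:
    n = len(g)
    w = params.window_snps
    if n < w:
        warnings.warn(f"chromosome {chrom}: {n} SNPs < window of {w}; skipped")
        return []
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    cum_het = np.concatenate([[0], np.cumsum(het)])
    cum_mis = np.concatenate([[0], np.cumsum(mis)])
    n_windows = n - w + 1
    starts = np.arange(n_windows)
    eligible = ((cum_het[starts + w] - cum_het[starts] <= params.max_het_per_window)
                & (cum_mis[starts + w] - cum_mis[starts] <= params.max_missing_per_window))
    cum_elig = np.concatenate([[0], np.cumsum(eligible.astype(np.int64))])

    # windows overlapping SNP i start in [max(0, i-w+1), min(i, n_windows-1)]
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_windows - 1)
    total = hi - lo + 1
    n_elig = cum_elig[hi + 1] - cum_elig[lo]
    score = n_elig / total

    candidate = (score >= params.min_prop_homozygous_windows) & (g != 1)

    segments: list[ROHSegment] = []
    cand_idx = np.flatnonzero(candidate)
    if len(cand_idx) == 0:
        return segments
    # split on index discontinuity or physical gap > max_gap_bp
    breaks = np.flatnonzero(
        (np.diff(cand_idx) > 1)
        | (np.diff(pos[cand_idx]) > params.max_gap_bp)
    )
    for run in np.split(cand_idx, breaks + 1):
        start_bp = int(pos[run[0]])
        end_bp = int(pos[run[-1]])
        length = end_bp - start_bp + 1
        n_run = len(run)
        if (length >= params.min_length_bp
                and n_run >= min_snps
                and n_run / length >= params.min_density_snp_per_bp):
            segments.append(ROHSegment(sample_id, chrom, start_bp, end_bp, n_run))
    return segments


def detect_all(
    matrix: GenotypeMatrix,
    params: ROHParams = ROHParams(),
    alpha: float = 0.05,
) -> tuple[list[ROHSegment], int]:
    """Detect ROHs for every individual; returns (segments, min_snps used)."""
    min_snps = resolve_min_snps(matrix, params, alpha)
    segments: list[ROHSegment] = []
    for sid in matrix.sample_ids:
        segments.extend(detect_roh(matrix, sid, params, min_snps))
    return segments, min_snps


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def bin_rohs(segments: Iterable[ROHSegment]) -> pd.Series:
    """Counts per length class; edges (0,0.1], (0.1,0.2], ... (1.6, inf) Mb."""
    counts = pd.Series(0, index=list(LENGTH_CLASS_LABELS), dtype=int)
    for seg in segments:
        counts[seg.length_class] += 1
    return counts


def roh_summaries(
    segments: Sequence[ROHSegment],
    genome: GenomeInfo,
    sample_ids: Sequence[str],
    density_window_bp: int = 1_000_000,
) -> dict[str, pd.DataFrame]:
    """Per-individual, per-chromosome and 1-Mb-density ROH summaries.

    Per-chromosome percentage is the summed ROH length of all individuals
    on that chromosome divided by (chromosome length x number of
    individuals) — i.e. the mean fraction of the chromosome inside an ROH
    per individual. Density counts segment midpoints per window.
    """
    for seg in segments:
        if seg.chrom not in genome.lengths:
            raise ValueError(f"segment on unknown chromosome {seg.chrom}")
        if seg.end > genome.lengths[seg.chrom]:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} beyond chromosome length"
            )
    n_ind = len(sample_ids)

    per_ind = {sid: [0, 0] for sid in sample_ids}
    for seg in segments:
        per_ind[seg.sample_id][0] += 1
        per_ind[seg.sample_id][1] += seg.length
    ind_df = pd.DataFrame(
        [(sid, c, l) for sid, (c, l) in per_ind.items()],
        columns=["sample_id", "n_rohs", "total_length_bp"],
    )

    chrom_rows = []
    for chrom, length in genome.lengths.items():
        segs = [s for s in segments if s.chrom == chrom]
        total = sum(s.length for s in segs)
        pct = 100.0 * total / (length * n_ind) if n_ind else 0.0
        chrom_rows.append((chrom, len(segs), total, pct))
    chrom_df = pd.DataFrame(
        chrom_rows, columns=["chrom", "n_rohs", "total_length_bp", "pct_covered"]
    )

    dens_rows = []
    for chrom, length in genome.lengths.items():
        n_bins = int(np.ceil(length / density_window_bp))
        counts = np.zeros(n_bins, dtype=int)
        for s in segments:
            if s.chrom == chrom:
                mid = (s.start + s.end) // 2
                counts[min((mid - 1) // density_window_bp, n_bins - 1)] += 1
        for b in range(n_bins):
            dens_rows.append((chrom, b * density_window_bp + 1,
                              min((b + 1) * density_window_bp, length), counts[b]))
    dens_df = pd.DataFrame(dens_rows, columns=["chrom", "start", "end", "n_rohs"])

    return {"per_individual": ind_df, "per_chromosome": chrom_df, "density": dens_df}
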