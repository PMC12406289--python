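"""Genomic inbreeding coefficients, ROH islands and selection-contrast statistics.

F_ROH is the genome fraction covered by an individual's ROH segments.
F_HOM is the excess of observed over HWE-expected homozygous genotypes,
(C_obs - C_exp) / (N - C_exp), with N the sample's non-missing genotype
count and C_exp summed over the same sites using the small-sample-corrected
expected homozygosity 1 - 2*p*q * 2n/(2n-1).

ROH islands are reported as merged intervals of "high-frequency" SNPs —
SNPs lying inside an ROH in more than a threshold fraction (default 50%)
of individuals — and are interpreted as candidate selective sweeps. The
three-way region contrast (island vs ROH vs non-ROH windows) compares
pooled heterozygosity Hp, Tajima's D and pi with two-sided Mann–Whitney U
tests.

Hp is computed from genotype-derived allele counts; its original
definition uses pooled read counts, but this package consumes genotypes,
and the substitution preserves the statistic's form and [0, 0.5] bounds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenomeInfo, GenotypeMatrix, ROHSegment
from .diversity import site_pi, window_starts


# ---------------------------------------------------------------------------
# inbreeding coefficients
# ---------------------------------------------------------------------------

def f_roh(
    segments: Iterable[ROHSegment],
    genome: GenomeInfo,
    sample_ids: Sequence[str],
) -> pd.Series:
    """Per-sample F_ROH = sum of ROH lengths / total genome length."""
    if genome.total == 0:
        raise ValueError("genome length is zero")
    total = pd.Series(0.0, index=list(sample_ids))
    for seg in segments:
        if seg.chrom not in genome.lengths:
            raise ValueError(f"segment on unknown chromosome {seg.chrom}")
        total[seg.sample_id] += seg.length
    return total / genome.total


@dataclass(frozen=True)
class HomozygosityRecord:
    """Observed/expected homozygous genotype counts for one sample."""

    sample_id: str
    c_observed: int
    c_expected: float
    n_genotypes: int

    @property
    def f_hom(self) -> float:
        denom = self.n_genotypes - self.c_expected
        if denom == 0:
            return float("nan")
        return (self.c_observed - self.c_expected) / denom


def f_hom(matrix: GenotypeMatrix) -> pd.DataFrame:
    """F_HOM (method-of-moments inbreeding coefficient) for every sample.

    Expected homozygosity per site uses the cohort allele frequency with
    the 2n/(2n-1) small-sample correction, summed over each sample's
    non-missing sites. Negative values indicate excess heterozygosity.
    """
    g = matrix.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(2 * n_called, 1)
        exp_hom_site = 1.0 - (2.0 * p * (1.0 - p)
                              * (2 * n_called) / np.maximum(2 * n_called - 1, 1))
    exp_hom_site = np.where(n_called > 0, exp_hom_site, 0.0)

    c_exp = called @ exp_hom_site
    n_geno = called.sum(axis=1)
    c_obs = ((g == 0) | (g == 2)).sum(axis=1)
    records = [
        HomozygosityRecord(sid, int(o), float(e), int(n))
        for sid, o, e, n in zip(matrix.sample_ids, c_obs, c_exp, n_geno)
    ]
    if any(r.n_genotypes == 0 for r in records):
        raise ValueError("sample with zero non-missing genotypes")
    return pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "c_observed": [r.c_observed for r in records],
        "c_expected": [r.c_expected for r in records],
        "n_genotypes": [r.n_genotypes for r in records],
        "f_hom": [r.f_hom for r in records],
    })


# ---------------------------------------------------------------------------
# ROH islands
# ---------------------------------------------------------------------------

def snp_occurrence_in_roh(
    segments: Iterable[ROHSegment], matrix: GenotypeMatrix
) -> np.ndarray:
    """Per-SNP fraction of individuals whose ROHs span the SNP position."""
    pos_all = matrix.sites["pos"].to_numpy()
    ranges = matrix.chrom_ranges()
    cover = np.zeros(matrix.n_sites, dtype=np.int64)
    # within one individual segments never overlap, so +1 per segment is
    # exactly "number of individuals covering the SNP"
    for seg in segments:
        if seg.chrom not in ranges:
            continue
        sl = ranges[seg.chrom]
        pos = pos_all[sl]
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="right")
        cover[sl.start + lo: sl.start + hi] += 1
    return cover / matrix.n_samples


@dataclass
class IslandInterval:
    """A merged run of high-frequency SNPs — a candidate ROH island."""

    chrom: str
    start: int
    end: int
    n_snps: int
    max_occurrence: float
    snp_positions: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    genes: list[dict] = field(default_factory=list)


def find_islands(
    occurrences: np.ndarray,
    matrix: GenotypeMatrix,
    threshold: float = 0.50,
    merge_gap_bp: int = 100_000,
) -> list[IslandInterval]:
    """Merge SNPs with occurrence strictly above ``threshold`` into intervals.

    Consecutive flagged SNPs on one chromosome at most ``merge_gap_bp``
    apart join one interval spanning the first to the last member SNP.
    """
    flagged = occurrences > threshold
    pos_all = matrix.sites["pos"].to_numpy()
    islands: list[IslandInterval] = []
    for chrom, sl in matrix.chrom_ranges().items():
        idx = np.flatnonzero(flagged[sl])
        if len(idx) == 0:
            continue
        pos = pos_all[sl][idx]
        occ = occurrences[sl][idx]
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        for run in np.split(np.arange(len(pos)), breaks + 1):
            islands.append(IslandInterval(
                chrom=chrom,
                start=int(pos[run[0]]),
                end=int(pos[run[-1]]),
                n_snps=len(run),
                max_occurrence=float(occ[run].max()),
                snp_positions=pos[run].copy(),
            ))
    return islands


def islands_to_frame(islands: Sequence[IslandInterval]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": i.chrom, "start": i.start, "end": i.end, "n_snps": i.n_snps,
         "max_occurrence": i.max_occurrence,
         "genes": ";".join(g["gene_id"] for g in i.genes) or "."}
        for i in islands
    ], columns=["chrom", "start", "end", "n_snps", "max_occurrence", "genes"])


def write_islands_bed(islands: Sequence[IslandInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in islands:
            fh.write(f"{i.chrom}\t{i.start - 1}\t{i.end}\t{i.n_snps}"
                     f"\t{i.max_occurrence:.4f}\n")


# ---------------------------------------------------------------------------
# window statistics: Hp and Tajima's D
# ---------------------------------------------------------------------------

def windowed_hp(
    matrix: GenotypeMatrix,
    window: int = 40_000,
    step: int = 20_000,
    genome: GenomeInfo | None = None,
) -> pd.DataFrame:
    """Pooled heterozygosity Hp = 2*S_maj*S_min / (S_maj + S_min)^2 per window.

    S_maj/S_min are the major/minor allele counts (from genotypes) summed
    over the window's SNPs. Windows with no called alleles report NaN.
    """
    ref, alt = matrix.allele_counts()
    n_maj = np.maximum(ref, alt).astype(float)
    n_min = np.minimum(ref, alt).astype(float)
    pos_all = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom, sl in matrix.chrom_ranges().items():
        pos = pos_all[sl]
        cmaj = np.concatenate([[0.0], np.cumsum(n_maj[sl])])
        cmin = np.concatenate([[0.0], np.cumsum(n_min[sl])])
        span_end = genome.lengths[chrom] if genome is not None else int(pos[-1])
        for start in window_starts(span_end, window, step):
            end = start + window
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            smaj = cmaj[hi] - cmaj[lo]
            smin = cmin[hi] - cmin[lo]
            tot = smaj + smin
            hp = 2.0 * smaj * smin / (tot * tot) if tot > 0 else np.nan
            rows.append((chrom, int(start), int(end - 1), int(hi - lo), hp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "hp"])


def tajima_constants(n: int) -> dict[str, float]:
    """The canonical a1, a2, b1, b2, c1, c2, e1, e2 for sample size n alleles."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(matrix: GenotypeMatrix, site_indices: np.ndarray) -> float:
    """Tajima's D over a set of sites; NaN when S = 0 or n < 4 alleles.

    The sample size n entering the constants is twice the modal number of
    co-called diploids across the sites; theta_pi uses each site's own
    allele counts.
    """
    g = matrix.genotypes[:, site_indices]
    called = g != MISSING
    n_called = called.sum(axis=0)
    if len(n_called) == 0 or n_called.max() == 0:
        return float("nan")
    vals, counts = np.unique(n_called[n_called > 0], return_counts=True)
    n = 2 * int(vals[np.argmax(counts)])
    if n < 4:
        return float("nan")
    ref = 2 * n_called - np.where(called, g, 0).sum(axis=0)
    alt = 2 * n_called - ref
    seg = (ref > 0) & (alt > 0)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_sites = np.where(
            n_called > 1,
            2.0 * ref * alt / (2.0 * n_called * (2.0 * n_called - 1.0)),
            0.0,
        )
    theta_pi = float(pi_sites.sum())
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (theta_pi - S / k["a1"]) / np.sqrt(var)


def windowed_tajima_d(
    matrix: GenotypeMatrix,
    window: int = 40_000,
    genome: GenomeInfo | None = None,
) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows; S = 0 windows report NaN."""
    pos_all = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom, sl in matrix.chrom_ranges().items():
        pos = pos_all[sl]
        span_end = genome.lengths[chrom] if genome is not None else int(pos[-1])
        for start in window_starts(span_end, window, window):
            end = start + window
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            idx = np.arange(sl.start + lo, sl.start + hi)
            d = tajima_d(matrix, idx) if len(idx) else float("nan")
            rows.append((chrom, int(start), int(end - 1), int(hi - lo), d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "tajima_d"])


# ---------------------------------------------------------------------------
# region contrast
# ---------------------------------------------------------------------------

def classify_windows(
    windows: pd.DataFrame,
    islands: Sequence[IslandInterval],
    segments: Sequence[ROHSegment],
) -> pd.Series:
    """Region class per window: island > roh > non-roh (priority order)."""
    by_chrom_isl: dict[str, list[tuple[int, int]]] = {}
    for i in islands:
        by_chrom_isl.setdefault(i.chrom, []).append((i.start, i.end))
    by_chrom_seg: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by_chrom_seg.setdefault(s.chrom, []).append((s.start, s.end))

    def overlaps(chrom: str, start: int, end: int,
                 table: dict[str, list[tuple[int, int]]]) -> bool:
        return any(s <= end and e >= start for s, e in table.get(chrom, ()))

    labels = []
    for row in windows.itertuples():
        if overlaps(row.chrom, row.start, row.end, by_chrom_isl):
            labels.append("island")
        elif overlaps(row.chrom, row.start, row.end, by_chrom_seg):
            labels.append("roh")
        else:
            labels.append("non-roh")
    return pd.Series(labels, index=windows.index, name="region")


def compare_regions(
    window_stats: pd.DataFrame,
    islands: Sequence[IslandInterval],
    segments: Sequence[ROHSegment],
    stat_cols: Sequence[str] = ("hp", "tajima_d", "pi"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-way contrast of window statistics across region classes.

    Returns (group summary, tests). Tests are two-sided Mann–Whitney U,
    island vs roh and island vs non-roh, per statistic; a comparison with
    an empty group is skipped with a warning.
    """
    region = classify_windows(window_stats, islands, segments)
    df = window_stats.copy()
    df["region"] = region

    summary_rows = []
    test_rows = []
    for stat in stat_cols:
        if stat not in df.columns:
            continue
        groups = {
            name: df.loc[df["region"] == name, stat].dropna().to_numpy()
            for name in ("island", "roh", "non-roh")
        }
        for name, vals in groups.items():
            summary_rows.append((stat, name, len(vals),
                                 float(np.median(vals)) if len(vals) else np.nan))
        for other in ("roh", "non-roh"):
            if len(groups["island"]) == 0 or len(groups[other]) == 0:
                warnings.warn(f"{stat}: empty group in island-vs-{other}; skipped")
                continue
            res = stats.mannwhitneyu(groups["island"], groups[other],
                                     alternative="two-sided")
            test_rows.append((stat, f"island_vs_{other.replace('-', '')}",
                              float(res.statistic), float(res.pvalue)))
    summary = pd.DataFrame(summary_rows, columns=["stat", "region", "n_windows", "median"])
    tests = pd.DataFrame(test_rows, columns=["stat", "comparison", "U", "p_value"])
    return summary, tests


# ---------------------------------------------------------------------------
# gene overlap
# ---------------------------------------------------------------------------

def _load_genes(gff_path: str | Path) -> tuple[pd.DataFrame, int]:
    """Gene features from a GFF3 file; malformed lines are skipped (counted)."""
    import gffutils

    kept_lines: list[str] = []
    n_skipped = 0
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                kept_lines.append(line)
                continue
            if len(line.rstrip("\n").split("\t")) == 9:
                kept_lines.append(line)
            else:
                n_skipped += 1
    db = gffutils.create_db(
        "".join(kept_lines), dbfn=":memory:", from_string=True,
        force=True, keep_order=True, merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name")
                   or [feat.id])[0]
        rows.append((str(feat.seqid), int(feat.start), int(feat.end), gene_id))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return genes, n_skipped


def map_genes(
    islands: Sequence[IslandInterval], gff_path: str | Path
) -> list[IslandInterval]:
    """Attach genes whose span intersects each island, with member-SNP counts.

    Returns the same island objects with ``genes`` filled: one dict per
    overlapping gene with gene_id, gene coordinates and the number of the
    island's member SNPs falling inside the gene.
    """
    genes, n_skipped = _load_genes(gff_path)
    if n_skipped:
        warnings.warn(f"{gff_path}: skipped {n_skipped} malformed GFF line(s)")
    for isl in islands:
        sub = genes[(genes["chrom"] == isl.chrom)
                    & (genes["start"] <= isl.end)
                    & (genes["end"] >= isl.start)]
        isl.genes = [
            {
                "gene_id": r.gene_id,
                "start": int(r.start),
                "end": int(r.end),
                "n_snps_in_gene": int(np.sum(
                    (isl.snp_positions >= r.start) & (isl.snp_positions <= r.end)
                )),
            }
            for r in sub.itertuples()
        ]
    return list(islands)


def genes_table(islands: Sequence[IslandInterval]) -> pd.DataFrame:
    """Candidate-gene table: gene, position, number of member SNPs inside."""
    rows = []
    for isl in islands:
        for g in isl.genes:
            rows.append((g["gene_id"], f"{isl.chrom}:{g['start']}-{g['end']}",
                         g["n_snps_in_gene"]))
    return pd.DataFrame(rows, columns=["gene", "position", "n_snps_in_roh"])
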