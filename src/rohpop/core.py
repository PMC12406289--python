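"""Shared data containers for diploid biallelic-SNP genotype analysis.

Genotypes are coded as copies of the ALT allele (0, 1, 2); missing calls use
the sentinel :data:`MISSING`. Positions are 1-based (VCF convention)
internally; every BED export converts to 0-based half-open coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: Upper edges (Mb) of the six ROH length classes; a boundary value belongs
#: to the lower class, the last class is open-ended.
LENGTH_CLASS_EDGES_MB: tuple[float, ...] = (0.1, 0.2, 0.4, 0.8, 1.6)
LENGTH_CLASS_LABELS: tuple[str, ...] = (
    "0-0.1", "0.1-0.2", "0.2-0.4", "0.4-0.8", "0.8-1.6", ">1.6",
)


class EmptyResultError(RuntimeError):
    """All sites or all individuals were removed by a filter."""


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid genotype matrix with site/sample metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_sites)`` int8 array of ALT-allele counts, -1 missing.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, id`` sorted by
        (chrom, pos); positions unique within a chromosome.
    samples
        DataFrame with columns ``sample_id, population``.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        pos = self.sites["pos"].to_numpy()
        for _, idx in self.chrom_ranges().items():
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError("sites must be sorted with unique positions per chromosome")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def sample_index(self, sample_id: str) -> int:
        hits = np.flatnonzero(self.samples["sample_id"].to_numpy() == sample_id)
        if len(hits) == 0:
            raise KeyError(f"unknown sample id: {sample_id}")
        return int(hits[0])

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.samples["population"].to_numpy() == population)
        if len(idx) == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx

    def chrom_ranges(self) -> dict[str, slice]:
        """Contiguous site-index slice per chromosome, in order of appearance."""
        chroms = self.sites["chrom"].to_numpy()
        out: dict[str, slice] = {}
        if len(chroms) == 0:
            return out
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                label = str(chroms[start])
                if label in out:
                    raise ValueError(f"chromosome {label} is not contiguous; sort the sites")
                out[label] = slice(start, i)
                start = i
        return out

    # -- subsetting --------------------------------------------------------
    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[:, keep], self.sites.iloc[keep], self.samples
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[keep], self.sites, self.samples.iloc[keep]
        )

    # -- derived quantities ------------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ref, alt) allele counts over non-missing calls."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = g != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        return 2 * n_called - alt, alt


@dataclass(frozen=True)
class GenomeInfo:
    """Chromosome labels and lengths in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    @property
    def total(self) -> int:
        return int(sum(self.lengths.values()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeInfo":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str}, comment="#")
        if len(df) and str(df.iloc[0, 0]).lower() in {"chrom", "chromosome"}:
            df = df.iloc[1:]
        return cls({str(r.chrom): int(r.length) for r in df.itertuples()})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.lengths.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity in one individual (1-based inclusive coords)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_class(self) -> str:
        mb = self.length / 1e6
        for edge, label in zip(LENGTH_CLASS_EDGES_MB, LENGTH_CLASS_LABELS):
            if mb <= edge:
                return label
        return LENGTH_CLASS_LABELS[-1]


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_snps, s.length, s.length_class)
        for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "n_snps", "length", "length_class"]
    )


def write_segments_bed(segments: Iterable[ROHSegment], path: str | Path) -> None:
    """BED export: 0-based half-open, columns chrom start end sample n_snps length."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.sample_id}\t{s.n_snps}\t{s.length}\n")


def read_segments_bed(path: str | Path) -> list[ROHSegment]:
    segs: list[ROHSegment] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start0, end, sample, n_snps = line.rstrip("\n").split("\t")[:5]
            segs.append(ROHSegment(sample, chrom, int(start0) + 1, int(end), int(n_snps)))
    return segs


def read_population_map(path: str | Path) -> dict[str, str]:
    """sample_id<TAB>population, optional header line."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {i + 1} is not sample_id<TAB>population")
            if i == 0 and fields[0].lower() in {"sample_id", "sample"}:
                continue
            mapping[fields[0]] = fields[1]
    return mapping
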