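"""Synthetic multi-population genotype simulator with known ground truth.

The simulator emulates a weakly differentiated wild cohort: several
populations whose allele frequencies are drawn around a shared ancestral
frequency under the Balding–Nichols model (Beta-distributed population
frequencies parameterised by F_ST), diploid genotypes drawn with an
inbreeding-adjusted Hardy–Weinberg law, irregular SNP spacing, optional
uniform missingness, and homozygous segments planted at known coordinates so
that downstream run-of-homozygosity detection can be scored against truth.

All randomness flows from a single seed in a fixed draw order
(positions -> alleles -> ancestral frequencies -> population frequencies ->
genotypes -> planted alleles -> missingness), so a fixed seed gives
byte-identical output files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import MISSING, GenomeInfo, GenotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All parameters of the synthetic-genotype generator.

    Defaults emulate the study conditions the package targets: four wild
    populations of comparable size with weak differentiation (low F_ST),
    dense irregular SNP spacing (~1 SNP per few hundred bp), per-site
    heterozygosity in the 0.25-0.37 range, and <=10% missingness.
    """

    n_populations: int = 4
    n_individuals_per_pop: int = 36
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    snp_spacing_bp: int = 300
    fst_target: float = 0.01
    maf_floor: float = 0.05
    missing_rate: float = 0.05
    #: (individual index, chromosome label, start bp, end bp) 1-based inclusive
    planted_rohs: list[tuple[int, str, int, int]] = field(default_factory=list)
    inbreeding_f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")
        n_ind = self.n_populations * self.n_individuals_per_pop
        labels = set(self.chrom_labels)
        by_ind: dict[int, list[tuple[int, int]]] = {}
        for ind, chrom, start, end in self.planted_rohs:
            if not 0 <= ind < n_ind:
                raise ValueError(f"planted ROH individual index {ind} out of range")
            if chrom not in labels:
                raise ValueError(f"planted ROH chromosome {chrom!r} not simulated")
            if not (1 <= start <= end <= self.chrom_length_bp):
                raise ValueError(
                    f"planted interval {chrom}:{start}-{end} outside chromosome bounds "
                    f"[1, {self.chrom_length_bp}]"
                )
            by_ind.setdefault(ind, []).append((start, end))
        for ind, ivals in by_ind.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"planted ROHs overlap within individual {ind}")

    @property
    def chrom_labels(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def n_individuals(self) -> int:
        return self.n_populations * self.n_individuals_per_pop

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_rohs" in raw:
            raw["planted_rohs"] = [tuple(x) for x in raw["planted_rohs"]]
        return cls(**raw)


@dataclass
class FrequencyTable:
    """Site coordinates plus ancestral and per-population ALT frequencies."""

    sites: pd.DataFrame                 # chrom, pos, ref, alt, id
    ancestral: np.ndarray               # (n_sites,)
    pop_freqs: np.ndarray               # (n_populations, n_sites)


@dataclass
class GroundTruth:
    planted_rohs: list[tuple[int, str, int, int]]
    true_roh_fraction: np.ndarray       # per individual
    ancestral_freq: np.ndarray
    pop_freqs: np.ndarray


def _simulate_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Irregularly spaced SNP coordinates: uniform draws, sorted, deduplicated."""
    frames = []
    for chrom in config.chrom_labels:
        n_target = max(1, round(config.chrom_length_bp / config.snp_spacing_bp))
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=n_target))
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "id": ".",
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_frequencies(config: SimulationConfig) -> FrequencyTable:
    """Draw ancestral and per-population ALT-allele frequencies.

    The ancestral frequency p is uniform on [maf_floor, 1 - maf_floor]; each
    population's frequency is Balding–Nichols
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = fst_target``. ``F = 0`` is
    short-circuited to copying the ancestral frequency (the Beta parameters
    would be infinite).
    """
    if not 0.0 <= config.fst_target <= 0.5:
        raise ValueError("fst_target must be in [0, 0.5] for frequency simulation")
    rng = np.random.default_rng(config.seed)
    sites = _simulate_sites(config, rng)
    n_sites = len(sites)
    p = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=n_sites)
    F = config.fst_target
    if F == 0.0:
        pop = np.tile(p, (config.n_populations, 1))
    else:
        scale = (1.0 - F) / F
        pop = rng.beta(p * scale, (1.0 - p) * scale,
                       size=(config.n_populations, n_sites))
    pop = np.clip(pop, 1e-9, 1.0 - 1e-9)
    return FrequencyTable(sites=sites, ancestral=p, pop_freqs=pop)


def simulate_genotypes(
    freqs: FrequencyTable, config: SimulationConfig
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw genotypes, plant homozygous segments, apply missingness.

    Genotypes follow inbreeding-adjusted Hardy–Weinberg probabilities
    (``q0^2 + F q0 q1``, ``2 q0 q1 (1-F)``, ``q1^2 + F q0 q1`` with ``F =
    inbreeding_f``). Planted intervals are then overwritten to homozygous at
    every spanned site, the allele drawn by population frequency, and are
    exempt from missingness so planted runs remain detectable.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_ind = config.n_individuals
    n_sites = len(freqs.sites)
    F = config.inbreeding_f

    geno = np.empty((n_ind, n_sites), dtype=np.int8)
    for k in range(config.n_populations):
        q = freqs.pop_freqs[k]
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("population frequencies must lie in (0, 1)")
        p0 = (1 - q) ** 2 + F * q * (1 - q)
        p01 = p0 + 2 * q * (1 - q) * (1 - F)
        rows = slice(k * config.n_individuals_per_pop, (k + 1) * config.n_individuals_per_pop)
        u = rng.random((config.n_individuals_per_pop, n_sites))
        geno[rows] = np.where(u < p0, 0, np.where(u < p01, 1, 2)).astype(np.int8)

    pop_of_ind = np.repeat(np.arange(config.n_populations), config.n_individuals_per_pop)
    chrom = freqs.sites["chrom"].to_numpy()
    pos = freqs.sites["pos"].to_numpy()
    planted_mask = np.zeros((n_ind, n_sites), dtype=bool)
    for ind, c, start, end in config.planted_rohs:
        in_ival = (chrom == c) & (pos >= start) & (pos <= end)
        idx = np.flatnonzero(in_ival)
        q = freqs.pop_freqs[pop_of_ind[ind], idx]
        alt = rng.random(len(idx)) < q
        geno[ind, idx] = np.where(alt, 2, 0).astype(np.int8)
        planted_mask[ind, idx] = True

    if config.missing_rate > 0:
        miss = rng.random((n_ind, n_sites)) < config.missing_rate
        miss &= ~planted_mask
        geno[miss] = MISSING

    samples = pd.DataFrame({
        "sample_id": [f"P{pop_of_ind[i] + 1}_I{i:03d}" for i in range(n_ind)],
        "population": [f"P{pop_of_ind[i] + 1}" for i in range(n_ind)],
    })
    matrix = GenotypeMatrix(geno, freqs.sites, samples)

    genome_total = config.n_chromosomes * config.chrom_length_bp
    frac = np.zeros(n_ind)
    for ind, _, start, end in config.planted_rohs:
        frac[ind] += (end - start + 1) / genome_total
    truth = GroundTruth(
        planted_rohs=list(config.planted_rohs),
        true_roh_fraction=frac,
        ancestral_freq=freqs.ancestral,
        pop_freqs=freqs.pop_freqs,
    )
    return matrix, truth


def simulate(config: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Convenience: frequencies + genotypes in one call."""
    return simulate_genotypes(simulate_frequencies(config), config)


def genome_info(config: SimulationConfig) -> GenomeInfo:
    return GenomeInfo({c: config.chrom_length_bp for c in config.chrom_labels})


def write_simulation(
    matrix: GenotypeMatrix, truth: GroundTruth, out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the VCF plus truth sidecars (BED of planted ROHs, per-individual TSV)."""
    from .vcfio import write_vcf  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "simulated.vcf",
        "truth_bed": out / "truth_rohs.bed",
        "truth_tsv": out / "truth_individuals.tsv",
        "popmap": out / "population_map.tsv",
    }
    contigs = None
    if config is not None:
        contigs = {c: config.chrom_length_bp for c in config.chrom_labels}
    write_vcf(matrix, paths["vcf"], contig_lengths=contigs)
    sample_ids = matrix.sample_ids
    with open(paths["truth_bed"], "w") as fh:
        for ind, chrom, start, end in truth.planted_rohs:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{sample_ids[ind]}\n")
    pd.DataFrame({
        "sample_id": sample_ids,
        "population": matrix.samples["population"],
        "true_roh_fraction": truth.true_roh_fraction,
    }).to_csv(paths["truth_tsv"], sep="\t", index=False, float_format="%.10g")
    with open(paths["popmap"], "w") as fh:
        for sid, pop in zip(sample_ids, matrix.samples["population"]):
            fh.write(f"{sid}\t{pop}\n")
    if config is not None:
        cfg_path = out / "simulation_config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=False)
        paths["config"] = cfg_path
    return paths
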