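"""Population-structure summaries: PCA, IBS/NJ tree, LD, Weir–Cockerham F_ST.

LD r^2 is the squared Pearson correlation of genotype dosages (composite
LD) — the only option for unphased data. The neighbor-joining
implementation is deterministic: ties in the Q matrix are broken by the
smallest (i, j) index pair and negative branch lengths are clamped to zero
with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix: GenotypeMatrix, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Allele-frequency-standardised PCA of the sample covariance matrix.

    Missing genotypes are mean-imputed per site; sites are centred by
    ``2*p`` and scaled by ``sqrt(2*p*q)`` (monomorphic sites dropped).
    Returns (scores DataFrame, % variance explained per retained component).
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    g = matrix.genotypes.astype(float)
    g[matrix.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    p = col_mean / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all sites are monomorphic")
    z = (g[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    cov = z @ z.T / z.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    k = min(n_components, len(eigval))
    scores = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        i_max = np.argmax(np.abs(scores[:, j]))
        if scores[i_max, j] < 0:
            scores[:, j] = -scores[:, j]
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "population", matrix.samples["population"].to_numpy())
    df.insert(0, "sample_id", matrix.sample_ids)
    return df, pct[:k]


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

def ibs_distance(matrix: GenotypeMatrix) -> pd.DataFrame:
    """1 - IBS distance matrix over all sample pairs.

    Per co-called site the allele-sharing score is 1 for identical
    genotypes, 0.5 when one allele overlaps, 0 for opposite homozygotes;
    IBS is its mean and distance = 1 - IBS.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    g = matrix.genotypes
    called = g != MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            co = called[i] & called[j]
            if not co.any():
                raise ValueError(
                    f"samples {matrix.sample_ids[i]} and {matrix.sample_ids[j]} "
                    "share no co-called sites"
                )
            share = 1.0 - np.abs(g[i, co].astype(float) - g[j, co]) / 2.0
            dist[i, j] = dist[j, i] = 1.0 - share.mean()
    return pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an (unrooted) NJ tree; leaves carry labels."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.label or ""
        inner = ",".join(f"{c._newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length distances between all leaf pairs (for additivity checks)."""
        pairs: dict[tuple[str, str], float] = {}

        def collect(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, 0.0)]
            groups = []
            for child, bl in node.children:
                groups.append([(name, d + bl) for name, d in collect(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for na, da in groups[gi]:
                        for nb, db in groups[gj]:
                            key = (na, nb) if na < nb else (nb, na)
                            pairs[key] = da + db
            return [x for grp in groups for x in grp]

        collect(self)
        names = sorted(self.leaf_names())
        mat = pd.DataFrame(0.0, index=names, columns=names)
        for (a, b), d in pairs.items():
            mat.loc[a, b] = mat.loc[b, a] = d
        return mat


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Canonical neighbor joining on a symmetric distance matrix.

    Produces an unrooted tree represented with a trifurcating root node.
    Q-matrix ties break on the smallest (i, j) pair; negative branch
    lengths are clamped to zero with a warning.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("NJ needs at least three taxa")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three nodes around one internal vertex
    (d01, d02, d12) = d[0, 1], d[0, 2], d[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """r^2 matrix over all column pairs with pairwise-complete observations.

    ``g`` is a (samples x sites) block with the missing sentinel; entries
    where either site is monomorphic among co-called samples are NaN.
    """
    called = (g != MISSING).astype(float)
    x = np.where(g == MISSING, 0, g).astype(float)
    n = called.T @ called
    sx = x.T @ called
    sxy = x.T @ x
    sxx = (x * x).T @ called
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sx.T
        var_x = n * sxx - sx ** 2
        den = var_x * var_x.T
        r2 = np.where((den > 0) & (n > 1), num ** 2 / np.where(den > 0, den, 1.0), np.nan)
    return r2


def _r2_one_vs_many(g: np.ndarray, a: int, b_lo: int, b_hi: int) -> np.ndarray:
    """r^2 of column ``a`` against columns [b_lo, b_hi), vectorised."""
    x = g[:, a]
    Y = g[:, b_lo:b_hi]
    cx = x != MISSING
    cy = Y != MISSING
    co = cx[:, None] & cy
    xf = np.where(cx, x, 0).astype(float)
    yf = np.where(cy, Y, 0).astype(float)
    n = co.sum(axis=0).astype(float)
    sx = (xf[:, None] * co).sum(axis=0)
    sy = (yf * co).sum(axis=0)
    sxy = (xf[:, None] * yf * co).sum(axis=0)
    sxx = ((xf ** 2)[:, None] * co).sum(axis=0)
    syy = (yf ** 2 * co).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx ** 2) * (n * syy - sy ** 2)
        return np.where((den > 0) & (n > 1), num ** 2 / np.where(den > 0, den, 1.0), np.nan)


def ld_r2(matrix: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """Squared Pearson correlation of genotype dosages over co-called samples.

    Returns NaN when either site is monomorphic in the co-called subset.
    """
    g = matrix.genotypes
    co = (g[:, site_i] != MISSING) & (g[:, site_j] != MISSING)
    x = g[co, site_i].astype(float)
    y = g[co, site_j].astype(float)
    if len(x) < 2 or x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay(
    matrix: GenotypeMatrix,
    max_dist: int = 300_000,
    bin_bp: int = 1_000,
    population: str | None = None,
) -> pd.DataFrame:
    """Mean r^2 per inter-SNP distance bin over all intra-chromosome pairs.

    Pairs where either site is monomorphic among co-called samples (within
    the population, when one is given) are skipped.
    """
    m = matrix if population is None else matrix.subset_samples(matrix.pop_indices(population))
    pos_all = m.sites["pos"].to_numpy()
    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    g = m.genotypes
    for _, sl in m.chrom_ranges().items():
        pos = pos_all[sl]
        offset = sl.start
        for a in range(len(pos)):
            hi = int(np.searchsorted(pos, pos[a] + max_dist, side="right"))
            if hi <= a + 1:
                continue
            r2 = _r2_one_vs_many(g, offset + a, offset + a + 1, offset + hi)
            dist = pos[a + 1:hi] - pos[a]
            ok = ~np.isnan(r2)
            if ok.any():
                bins = (dist[ok] - 1) // bin_bp
                np.add.at(sums, bins, r2[ok])
                np.add.at(counts, bins, 1)
    rows = [
        (i * bin_bp + 1, (i + 1) * bin_bp, counts[i], sums[i] / counts[i])
        for i in range(n_bins) if counts[i] > 0
    ]
    return pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "n_pairs", "mean_r2"])


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """PLINK-style pairwise pruning; returns retained site indices.

    Sliding windows of ``window`` SNPs advanced by ``step``; within each
    window every (i, j) pair (lexicographic order) with r^2 > ``r2_max``
    removes the later site. Removals accumulate genome-wide.
    """
    removed = np.zeros(matrix.n_sites, dtype=bool)
    for _, sl in matrix.chrom_ranges().items():
        lo, hi = sl.start, sl.stop
        start = lo
        while True:
            end = min(start + window, hi)
            active = [k for k in range(start, end) if not removed[k]]
            if len(active) > 1:
                r2 = _pairwise_r2(matrix.genotypes[:, active])
                for ai in range(len(active)):
                    if removed[active[ai]]:
                        continue
                    for aj in range(ai + 1, len(active)):
                        if removed[active[aj]]:
                            continue
                        if r2[ai, aj] > r2_max:  # NaN compares False
                            removed[active[aj]] = True
            if end >= hi:
                break
            start += step
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------

def pairwise_fst(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[pd.DataFrame, float]:
    """Weir–Cockerham (1984) two-population F_ST.

    Returns the per-site estimates and the genome-wide value computed as
    the ratio of summed variance components (not a mean of ratios). Sites
    monomorphic across both populations, or with fewer than two genotyped
    samples in either population, are excluded.
    """
    idx_a = matrix.pop_indices(pop_a)
    idx_b = matrix.pop_indices(pop_b)
    g = matrix.genotypes
    comps = []
    for idx in (idx_a, idx_b):
        sub = g[idx]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)              # genotyped diploids
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / np.maximum(2 * n, 1)
            h = ((sub == 1) & called).sum(axis=0) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    ok = (n1 >= 2) & (n2 >= 2)
    poly = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    ok &= poly

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        per_site = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    df = matrix.sites.loc[ok, ["chrom", "pos"]].copy()
    df["fst"] = per_site[ok]
    genome_wide = float(a[ok].sum() / denom[ok].sum())
    return df.reset_index(drop=True), genome_wide
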