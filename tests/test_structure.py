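"""PCA, IBS distance, neighbor joining, LD and Weir–Cockerham F_ST."""
import numpy as np
import pytest
from scipy import stats as sps

from rohpop.core import MISSING
from rohpop.structure import (
    TreeNode,
    ibs_distance,
    ld_decay,
    ld_prune,
    ld_r2,
    nj_tree,
    pairwise_fst,
    pca,
)
from rohpop.synthio import SimulationConfig, simulate


# ---------------------------------------------------------------------------
# tree helpers (test-side oracle)
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa, rng):
    """Random binary unrooted tree; returns (networkx graph, leaf names)."""
    import networkx as nx

    g = nx.Graph()
    leaves = [f"t{i}" for i in range(n_taxa)]
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        inner = f"n{nxt}"
        nxt += 1
        g.add_edge(nodes[i], inner, weight=float(rng.uniform(0.05, 1.0)))
        g.add_edge(nodes[j], inner, weight=float(rng.uniform(0.05, 1.0)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [inner]
    center = f"n{nxt}"
    for v in nodes:
        g.add_edge(v, center, weight=float(rng.uniform(0.05, 1.0)))
    return g, leaves


def graph_distance_matrix(g, leaves):
    import networkx as nx
    import pandas as pd

    d = pd.DataFrame(0.0, index=leaves, columns=leaves)
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for a in leaves:
        for b in leaves:
            d.loc[a, b] = paths[a][b]
    return (d + d.T) / 2.0  # remove float asymmetry from path summation order


def tree_splits(node: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions (as the smaller-side leaf sets) of a tree."""
    all_leaves = frozenset(node.leaf_names())
    splits = set()

    def walk(n: TreeNode):
        if n.is_leaf:
            return frozenset([n.label])
        below = frozenset()
        for child, _ in n.children:
            sub = walk(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                splits.add(min(sub, all_leaves - sub, key=sorted))
            below |= sub
        return below

    walk(node)
    return splits


def graph_splits(g, leaves) -> set[frozenset]:
    import networkx as nx

    all_leaves = frozenset(leaves)
    splits = set()
    for e in list(g.edges()):
        h = g.copy()
        h.remove_edge(*e)
        comp = frozenset(x for x in nx.node_connected_component(h, e[0]) if x in all_leaves)
        if 1 < len(comp) < len(all_leaves) - 1:
            splits.add(min(comp, all_leaves - comp, key=sorted))
    return splits


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_separates_differentiated_populations(self):
        cfg = SimulationConfig(n_populations=2, n_individuals_per_pop=20,
                               n_chromosomes=1, chrom_length_bp=1_000_000,
                               snp_spacing_bp=500, fst_target=0.2,
                               missing_rate=0.02, seed=11)
        m, _ = simulate(cfg)
        scores, _ = pca(m)
        pc1 = scores.set_index("population")["PC1"]
        a, b = pc1.loc["P1"], pc1.loc["P2"]
        assert a.max() < b.min() or b.max() < a.min()

    def test_duplicated_sample_identical_scores(self, mk, rng):
        g = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        g[5] = g[0]
        scores, _ = pca(mk(g))
        assert np.allclose(scores.iloc[0, 2:].to_numpy(dtype=float),
                           scores.iloc[5, 2:].to_numpy(dtype=float), atol=1e-9)

    def test_variance_shares_sum_to_100(self, mk, rng):
        g = rng.integers(0, 3, size=(7, 60)).astype(np.int8)
        m = mk(g)
        _, pct = pca(m, n_components=7)
        assert np.all(pct >= 0)
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_monomorphic_rejected(self, mk):
        with pytest.raises(ValueError, match="monomorphic"):
            pca(mk(np.zeros((4, 10), dtype=np.int8)))


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

class TestIBS:
    def test_identical_individuals(self, mk, rng):
        g = rng.integers(0, 3, size=(1, 50)).astype(np.int8)
        m = mk(np.vstack([g, g]))
        assert ibs_distance(m).iloc[0, 1] == 0.0

    def test_opposite_homozygotes(self, mk):
        g = np.vstack([np.zeros(20), np.full(20, 2)]).astype(np.int8)
        assert ibs_distance(mk(g)).iloc[0, 1] == 1.0

    def test_matches_per_site_tally(self, mk, rng):
        for _ in range(10):
            g = rng.integers(-1, 3, size=(5, 30)).astype(np.int8)
            # ensure every pair shares a co-called site
            g[:, 0] = 1
            d = ibs_distance(mk(g))
            for i in range(5):
                for j in range(i + 1, 5):
                    shares, n = 0.0, 0
                    for s in range(30):
                        if g[i, s] == MISSING or g[j, s] == MISSING:
                            continue
                        n += 1
                        shares += 1.0 - abs(int(g[i, s]) - int(g[j, s])) / 2.0
                    assert d.iloc[i, j] == pytest.approx(1 - shares / n, abs=1e-12)

    def test_no_cocalled_pair_errors(self, mk):
        g = np.array([[0, MISSING], [MISSING, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="co-called"):
            ibs_distance(mk(g))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNJ:
    def test_three_taxa_closed_form(self):
        import pandas as pd
        d = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tree = nj_tree(d)
        bl = {c.label: l for c, l in tree.children}
        assert bl["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert bl["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert bl["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_tree_recovery(self, rng):
        for _ in range(10):
            g, leaves = random_additive_tree(8, rng)
            d = graph_distance_matrix(g, leaves)
            tree = nj_tree(d)
            assert tree_splits(tree) == graph_splits(g, leaves)
            rec = tree.leaf_distances().loc[d.index, d.columns]
            assert np.allclose(rec.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_taxon_order_invariance(self, rng):
        g, leaves = random_additive_tree(7, rng)
        d = graph_distance_matrix(g, leaves)
        perm = list(rng.permutation(leaves))
        t1 = nj_tree(d)
        t2 = nj_tree(d.loc[perm, perm])
        assert tree_splits(t1) == tree_splits(t2)

    def test_agrees_with_skbio(self, rng):
        """Independent cross-check of the topology against scikit-bio."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        g, leaves = random_additive_tree(8, rng)
        d = graph_distance_matrix(g, leaves)
        ours = tree_splits(nj_tree(d))
        sk_tree = sk_nj(SkDM(d.to_numpy(), ids=list(d.index)))
        all_leaves = frozenset(leaves)
        theirs = set()
        for node in sk_tree.non_tips():
            sub = frozenset(t.name for t in node.tips())
            if 1 < len(sub) < len(all_leaves) - 1:
                theirs.add(min(sub, all_leaves - sub, key=sorted))
        assert ours == theirs

    def test_non_symmetric_rejected(self):
        import pandas as pd
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

class TestLD:
    def test_duplicated_site_r2_one(self, mk, rng):
        col = rng.integers(0, 3, size=8).astype(np.int8)
        while len(set(col)) == 1:
            col = rng.integers(0, 3, size=8).astype(np.int8)
        m = mk(np.stack([col, col], axis=1))
        assert ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self, mk):
        m = mk(np.array([[0, 2], [0, 2], [1, 1], [2, 0]], dtype=np.int8))
        assert ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_matches_pearson_oracle(self, mk, rng):
        for _ in range(20):
            g = rng.integers(-1, 3, size=(40, 2)).astype(np.int8)
            m = mk(g)
            co = (g[:, 0] != MISSING) & (g[:, 1] != MISSING)
            x, y = g[co, 0].astype(float), g[co, 1].astype(float)
            ours = ld_r2(m, 0, 1)
            if co.sum() < 2 or x.std() == 0 or y.std() == 0:
                assert np.isnan(ours)
            else:
                r, _ = sps.pearsonr(x, y)
                assert ours == pytest.approx(r * r, abs=1e-10)

    def test_monomorphic_pair_skipped(self, mk):
        m = mk(np.array([[0, 1], [0, 0], [0, 2]], dtype=np.int8))
        assert np.isnan(ld_r2(m, 0, 1))

    def test_decay_block_fixture(self, mk, rng):
        # adjacent duplicated SNPs -> near-1 mean r2 in the first bin
        col = rng.integers(0, 3, size=30).astype(np.int8)
        col[0] = 0
        col[1] = 2
        g = np.stack([col, col, rng.integers(0, 3, size=30).astype(np.int8)], axis=1)
        m = mk(g, positions=[1000, 1500, 250_000])
        df = ld_decay(m, max_dist=300_000, bin_bp=1000)
        first = df[df["dist_lo"] == 1]
        assert first["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_decay_boundary_exclusion(self, mk, rng):
        col = rng.integers(0, 3, size=12).astype(np.int8)
        g = np.stack([col, col], axis=1)
        m = mk(g, positions=[1, 300_002])  # distance 300,001 > max
        assert len(ld_decay(m, max_dist=300_000)) == 0

    def test_decay_single_snp_empty(self, mk):
        m = mk(np.array([[1], [0]], dtype=np.int8))
        assert len(ld_decay(m)) == 0

    def test_prune_uncorrelated_keeps_all(self, mk, rng):
        g = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        m = mk(g)
        from rohpop.structure import _pairwise_r2
        r2 = _pairwise_r2(g)
        np.fill_diagonal(r2, 0.0)
        if np.nanmax(r2) <= 0.5:  # holds at this n with high probability
            kept = ld_prune(m)
            assert len(kept) == 10

    def test_prune_removes_one_duplicate(self, mk, rng):
        col = rng.integers(0, 3, size=50).astype(np.int8)
        g = np.stack([col, col, rng.integers(0, 3, size=50).astype(np.int8)], axis=1)
        kept = ld_prune(mk(g))
        assert 0 in kept and 1 not in kept

    def test_prune_fixed_point_and_posthoc(self, mk, rng):
        g = rng.integers(0, 3, size=(30, 60)).astype(np.int8)
        g[:, 10] = g[:, 9]
        g[:, 30] = g[:, 29]
        m = mk(g)
        kept = ld_prune(m, window=20, step=5, r2_max=0.5)
        pruned = m.subset_sites(kept)
        kept2 = ld_prune(pruned, window=20, step=5, r2_max=0.5)
        assert len(kept2) == pruned.n_sites  # fixed point
        # exhaustive post-hoc: no within-window pair above the threshold
        from rohpop.structure import _pairwise_r2
        for s in range(0, pruned.n_sites - 1, 5):
            block = pruned.genotypes[:, s:s + 20]
            r2 = _pairwise_r2(block)
            iu = np.triu_indices(block.shape[1], k=1)
            vals = r2[iu]
            assert not np.any(vals[~np.isnan(vals)] > 0.5)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFst:
    def test_no_differentiation_near_zero(self):
        cfg = SimulationConfig(n_populations=2, n_individuals_per_pop=100,
                               n_chromosomes=1, chrom_length_bp=2_000_000,
                               snp_spacing_bp=400, fst_target=0.0,
                               missing_rate=0.0, seed=13)
        m, _ = simulate(cfg)
        _, fst = pairwise_fst(m, "P1", "P2")
        assert abs(fst) < 0.01

    def test_fixed_difference_is_one(self, mk):
        g = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)]).astype(np.int8)
        m = mk(g, populations=["A"] * 10 + ["B"] * 10)
        per_site, gw = pairwise_fst(m, "A", "B")
        assert np.allclose(per_site["fst"], 1.0)
        assert gw == pytest.approx(1.0)

    def test_symmetry(self, mk, rng):
        g = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        m = mk(g, populations=["A"] * 10 + ["B"] * 10)
        _, ab = pairwise_fst(m, "A", "B")
        _, ba = pairwise_fst(m, "B", "A")
        assert ab == pytest.approx(ba, abs=1e-12)
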