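import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from neurotraj import clustering as cl
from neurotraj import qc


def brute_force_mknn(coords, k):
    """O(n^2) mutual-kNN oracle with the same tie-break (index order)."""
    n = len(coords)
    corr = np.corrcoef(coords)
    neighbors = []
    for i in range(n):
        cand = [(-corr[i, j], j) for j in range(n) if j != i]
        cand.sort()
        neighbors.append({j for _, j in cand[:k]})
    edges = {(i, j) for i in range(n) for j in neighbors[i]
             if i < j and i in neighbors[j]}
    return edges


def make_norm(values):
    values = np.asarray(values, float)
    return qc.NormalizedMatrix(values, [f"G{i}" for i in range(values.shape[0])],
                               [f"B{i}" for i in range(values.shape[1])],
                               np.ones(values.shape[1]))


class TestPCA:
    def test_rank_two_plane_has_no_extra_variance(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 12))
        scores = rng.normal(size=(40, 2))
        values = (scores @ basis).T  # genes x nuclei, rank 2
        norm = make_norm(values)
        emb = cl.embed_pca(norm, norm.genes, d=5)
        rel = emb.explained_variance / emb.explained_variance[0]
        assert np.all(rel[2:] < 1e-8)

    def test_reconstruction_from_all_pcs(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 30))  # genes x nuclei
        norm = make_norm(values)
        emb = cl.embed_pca(norm, norm.genes, d=10)
        X = values.T
        centered = X - X.mean(axis=0)
        recon = emb.coords @ emb.loadings.T
        assert np.allclose(recon, centered, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(15, 40))
        emb1 = cl.embed_pca(make_norm(values), None, d=4)
        emb2 = cl.embed_pca(make_norm(values.copy()), None, d=4)
        assert np.allclose(emb1.coords, emb2.coords)
        for j in range(4):
            i_max = np.argmax(np.abs(emb1.loadings[:, j]))
            assert emb1.loadings[i_max, j] > 0

    def test_d_exceeding_rank_errors(self):
        values = np.random.default_rng(3).normal(size=(5, 8))
        with pytest.raises(ValueError):
            cl.embed_pca(make_norm(values), None, d=6)


class TestMutualKnnGraph:
    def test_hand_written_six_points(self):
        coords = np.array([
            [0.0, 1.0, 2.0], [0.1, 1.1, 2.0], [0.0, 1.0, 2.5],
            [5.0, 1.0, 0.0], [5.2, 1.1, 0.0], [2.0, 3.0, 1.0],
        ])
        edges, _ = cl.build_mknn_graph_from_coords(coords, k=2)
        got = {tuple(e) for e in edges}
        assert got == brute_force_mknn(coords, 2)

    @pytest.mark.parametrize("k", [2, 5, 40])
    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_on_random_fixtures(self, k, trial):
        rng = np.random.default_rng(100 * k + trial)
        n = int(rng.integers(k + 2, 120))
        coords = rng.normal(size=(n, 6))
        edges, weights = cl.build_mknn_graph_from_coords(coords, k)
        got = {tuple(e) for e in edges}
        assert got == brute_force_mknn(coords, k)
        corr = np.corrcoef(coords)
        for (i, j), w in zip(edges, weights):
            assert w == pytest.approx(corr[i, j])

    def test_saturated_k_gives_complete_graph(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(12, 5))
        edges, _ = cl.build_mknn_graph_from_coords(coords, k=11)
        assert len(edges) == 12 * 11 // 2

    def test_constant_row_errors_with_index(self):
        coords = np.random.default_rng(5).normal(size=(10, 4))
        coords[3] = 2.0
        with pytest.raises(ValueError, match="3"):
            cl.build_mknn_graph_from_coords(coords, k=2)

    def test_too_few_nuclei_errors(self):
        with pytest.raises(ValueError):
            cl.build_mknn_graph_from_coords(np.random.default_rng(6).normal(size=(4, 3)), k=5)


def graph_of(coords, k, ids=None):
    edges, weights = cl.build_mknn_graph_from_coords(coords, k)
    ids = ids or [f"B{i}" for i in range(len(coords))]
    return cl.SimilarityGraph(ids=ids, edges=edges, weights=weights, k=k)


class TestPruneComponents:
    def test_connected_graph_keeps_everything(self):
        rng = np.random.default_rng(7)
        g = graph_of(rng.normal(size=(50, 4)), k=49)
        pruned, discarded = cl.prune_small_components(g, 30)
        assert discarded == [] and pruned.n_nodes == 50

    def test_strict_inequality_at_boundary(self):
        # components of sizes {100, 30, 5}: the 30- and 5-node ones go
        sizes = [100, 30, 5]
        edges = []
        offset = 0
        for s in sizes:
            edges += [(offset + i, offset + i + 1) for i in range(s - 1)]
            offset += s
        g = cl.SimilarityGraph(ids=[f"B{i}" for i in range(135)],
                               edges=np.array(edges),
                               weights=np.ones(len(edges)), k=1)
        pruned, discarded = cl.prune_small_components(g, 30)
        assert pruned.n_nodes == 100
        assert len(discarded) == 35

    def test_two_blob_discard_depends_on_threshold(self):
        # two orthogonal correlation patterns -> no cross-blob edges
        rng = np.random.default_rng(8)
        p1 = np.array([10.0, 0.0, 10.0, 0.0, 10.0, 0.0])
        p2 = np.array([0.0, 10.0, 0.0, 10.0, 0.0, 10.0])
        a = p1 + rng.normal(0, 1, size=(200, 6))
        b = p2 + rng.normal(0, 1, size=(40, 6))
        coords = np.vstack([a, b])
        g = graph_of(coords, k=10)
        # verify the construction really has no cross edges
        cross = [(i, j) for i, j in g.edges if (i < 200) != (j < 200)]
        assert not cross
        blob_b = {f"B{i}" for i in range(200, 240)}
        _, disc30 = cl.prune_small_components(g, 30)
        assert not (set(disc30) & blob_b)  # the 40-node blob survives at 30
        _, disc50 = cl.prune_small_components(g, 50)
        assert blob_b <= set(disc50)       # and is discarded at 50


class TestLouvain:
    def test_two_cliques_give_two_communities(self):
        edges = [(i, j) for i, j in itertools.combinations(range(6), 2)]
        edges += [(i + 6, j + 6) for i, j in itertools.combinations(range(6), 2)]
        edges += [(0, 6)]
        g = cl.SimilarityGraph(ids=[f"B{i}" for i in range(12)],
                               edges=np.array(edges),
                               weights=np.ones(len(edges)), k=5)
        part = cl.louvain_partition(g, seed=0)
        labels = part.labels
        assert len(set(labels)) == 2
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(9)
        centers = rng.normal(0, 6, size=(10, 8))
        coords = np.vstack([c + rng.normal(0, 1, size=(120, 8))
                            for c in centers])
        truth = np.repeat(np.arange(10), 120)
        g = graph_of(coords, k=15)
        part = cl.louvain_partition(g, seed=0)
        assert adjusted_rand_score(truth, part.labels) >= 0.8

    def test_resolution_weakly_increases_communities(self):
        rng = np.random.default_rng(10)
        coords = np.vstack([c + rng.normal(0, 1.5, size=(60, 6))
                            for c in rng.normal(0, 5, size=(6, 6))])
        g = graph_of(coords, k=12)
        counts = [len(set(cl.louvain_partition(g, resolution=r, seed=0).labels))
                  for r in [0.2, 1.0, 4.0]]
        assert counts[0] <= counts[1] <= counts[2]

    def test_modularity_beats_trivial_partitions(self):
        rng = np.random.default_rng(11)
        coords = np.vstack([rng.normal(0, 1, size=(60, 5)),
                            rng.normal(8, 1, size=(60, 5))])
        g = graph_of(coords, k=10)
        part = cl.louvain_partition(g, seed=0)
        ig_g = g.to_igraph()
        singleton = ig_g.modularity(list(range(g.n_nodes)), weights="weight")
        one = ig_g.modularity([0] * g.n_nodes, weights="weight")
        members = {n: i for i, n in enumerate(sorted(set(part.labels)))}
        assert part.modularity >= singleton
        assert part.modularity >= one

    def test_empty_graph_errors(self):
        g = cl.SimilarityGraph(ids=[], edges=np.zeros((0, 2), int),
                               weights=np.zeros(0), k=1)
        with pytest.raises(ValueError):
            cl.louvain_partition(g)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(150, 5))
        g = graph_of(coords, k=10)
        a = cl.louvain_partition(g, seed=3)
        b = cl.louvain_partition(g, seed=3)
        assert list(a.labels) == list(b.labels)


@pytest.fixture(scope="module")
def four_group_norm():
    """Four discrete expression programs, one exclusive marker each."""
    rng = np.random.default_rng(13)
    n_per, n_genes = 60, 200
    values = rng.normal(1.0, 0.3, size=(n_genes, 4 * n_per))
    for g in range(4):
        sl = slice(g * n_per, (g + 1) * n_per)
        values[g * 20:(g + 1) * 20, sl] += 3.0   # block program
        values[180 + g, sl] += 5.0               # exclusive marker
    norm = make_norm(values)
    labels = np.repeat([f"K{i}" for i in range(4)], n_per).astype(object)
    part = cl.ClusterPartition(list(norm.barcodes), labels)
    return norm, part


class TestDifferentialExpression:
    def test_random_split_of_one_population_yields_no_degs(self, four_group_norm):
        norm, part = four_group_norm
        members = part.members("K0")
        rng = np.random.default_rng(14)
        rng.shuffle(members)
        t = cl.differential_expression(norm, None, members[:30], members[30:])
        assert t["significant"].sum() == 0

    def test_overlapping_groups_rejected(self, four_group_norm):
        norm, part = four_group_norm
        m = part.members("K0")
        with pytest.raises(ValueError, match="overlap"):
            cl.differential_expression(norm, None, m[:30], m[20:40])

    def test_planted_shift_recall_and_fdr(self):
        rng = np.random.default_rng(15)
        n_genes = 2000
        values = rng.normal(2.0, 0.5, size=(n_genes, 400))
        up = rng.choice(n_genes, 100, replace=False)
        values[np.ix_(up, np.arange(200))] += 1.0  # 2-fold on log2 scale
        norm = make_norm(values)
        t = cl.differential_expression(norm, None,
                                       norm.barcodes[:200], norm.barcodes[200:])
        called = set(t.loc[t["significant"], "gene"])
        planted = {f"G{i}" for i in up}
        recall = len(called & planted) / 100
        fdr = len(called - planted) / max(len(called), 1)
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_swap_symmetry(self, four_group_norm):
        norm, part = four_group_norm
        ab = cl.differential_expression(norm, part, "K0", "K1")
        ba = cl.differential_expression(norm, part, "K1", "K0")
        assert np.allclose(ab["log2FC"], -ba["log2FC"])
        assert np.allclose(ab["q"], ba["q"])

    def test_q_never_below_p(self, four_group_norm):
        norm, part = four_group_norm
        t = cl.differential_expression(norm, part, "K0", "K2")
        assert (t["q"] >= t["p"] - 1e-15).all()


class TestRefinePartition:
    def test_distinct_clusters_are_fixed_point(self, four_group_norm):
        norm, part = four_group_norm
        refined = cl.refine_partition(part, norm)
        assert list(refined.labels) == list(part.labels)

    def test_artificial_split_is_merged_back(self, four_group_norm):
        norm, part = four_group_norm
        labels = part.labels.copy()
        k0 = np.where(labels == "K0")[0]
        labels[k0[:30]] = "K0a"
        labels[k0[30:]] = "K0b"
        split = cl.ClusterPartition(part.ids, labels)
        refined = cl.refine_partition(split, norm)
        merged = set(refined.labels[k0])
        assert len(merged) == 1
        assert len(set(refined.labels)) == 4

    def test_merge_is_scan_order_insensitive(self, four_group_norm):
        norm, part = four_group_norm
        labels = part.labels.copy()
        k0 = np.where(labels == "K0")[0]
        labels[k0[:30]] = "Ka"
        labels[k0[30:]] = "Kb"
        p1 = cl.ClusterPartition(part.ids, labels)
        # reversed presentation of the same partition
        order = np.arange(len(labels))[::-1]
        p2 = cl.ClusterPartition([part.ids[i] for i in order], labels[order])
        r1 = cl.refine_partition(p1, norm)
        n2 = norm.subset_barcodes(list(p2.ids))
        r2 = cl.refine_partition(p2, n2)
        m1 = dict(zip(r1.ids, r1.labels))
        m2 = dict(zip(r2.ids, r2.labels))
        assert m1 == m2


class TestMarkers:
    def test_exclusive_gene_is_rank_one(self, four_group_norm):
        norm, part = four_group_norm
        markers = cl.rank_markers(norm, part, top_m=5)
        for g in range(4):
            top = markers[(markers["cluster"] == f"K{g}")
                          & (markers["rank"] == 1)]["gene"].iloc[0]
            assert top == f"G{180 + g}"

    def test_marker_lists_disjoint_for_disjoint_programs(self, four_group_norm):
        norm, part = four_group_norm
        markers = cl.rank_markers(norm, part, top_m=5)
        lists = [set(markers[markers["cluster"] == c]["gene"])
                 for c in ["K0", "K1", "K2", "K3"]]
        for a, b in itertools.combinations(lists, 2):
            assert not (a & b)
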