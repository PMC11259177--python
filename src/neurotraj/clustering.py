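"""PCA embedding, mutual-kNN graph construction, Louvain clustering with
merge-based refinement, and pairwise differential expression / markers.

The similarity measure throughout is the Pearson correlation between
nuclei in the subspace of the top principal components (d = 20 by
default); the graph keeps an edge only when two nuclei are mutually among
each other's k = 40 nearest neighbors, and connected components with 30 or
fewer nodes are discarded before community detection.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    coords: np.ndarray              # nuclei x d PC scores
    loadings: np.ndarray            # genes x d
    explained_variance: np.ndarray  # length d, decreasing
    ids: list[str]                  # nucleus barcodes
    genes: list[str]                # HVGs the PCA was fit on


@dataclass
class SimilarityGraph:
    ids: list[str]
    edges: np.ndarray    # m x 2 int array, i < j
    weights: np.ndarray  # Pearson correlations in [-1, 1]
    k: int

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def to_igraph(self, clip_negative: bool = True) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        w = np.clip(self.weights, 0.0, None) if clip_negative else self.weights
        g.es["weight"] = list(w)
        return g


@dataclass
class ClusterPartition:
    ids: list[str]
    labels: np.ndarray  # object array of cluster names, one per id
    lineage_order: list[str] = field(default_factory=list)
    modularity: float | None = None
    merge_log: list[str] = field(default_factory=list)

    def members(self, cluster: str) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == cluster]

    def cluster_names(self) -> list[str]:
        return sorted(set(map(str, self.labels)))

    def rename(self, mapping: dict[str, str]) -> "ClusterPartition":
        labels = np.array([mapping.get(str(l), str(l)) for l in self.labels],
                          dtype=object)
        return ClusterPartition(list(self.ids), labels,
                                list(self.lineage_order), self.modularity,
                                list(self.merge_log))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.ids, "cluster": self.labels})


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def embed_pca(norm: NormalizedMatrix, hvg_set: list[str] | None = None,
              d: int = 20) -> Embedding:
    """Centered PCA on the HVG submatrix with a deterministic sign
    convention (the largest-|loading| entry of each component is positive)."""
    genes = hvg_set if hvg_set is not None else (norm.hvg_set or norm.genes)
    if len(genes) < d:
        raise ValueError(f"need at least d={d} HVGs, got {len(genes)}")
    X = norm.subset_genes(list(genes)).T  # nuclei x genes
    n, p = X.shape
    max_rank = min(n - 1, p)
    if d > max_rank:
        raise ValueError(f"d={d} exceeds the maximum possible rank {max_rank}")
    solver = "full" if min(n, p) <= 600 else "randomized"
    pca = PCA(n_components=d, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(X - X.mean(axis=0))
    loadings = pca.components_.T  # genes x d
    for j in range(d):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return Embedding(coords=scores, loadings=loadings,
                     explained_variance=pca.explained_variance_,
                     ids=list(norm.barcodes), genes=list(genes))


# ---------------------------------------------------------------------------
# Mutual kNN graph
# ---------------------------------------------------------------------------

def _row_correlations(coords: np.ndarray) -> np.ndarray:
    sd = coords.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        raise ValueError(
            f"nucleus index {bad} has constant PC coordinates; "
            "Pearson correlation is undefined")
    return np.corrcoef(coords)


def build_mknn_graph_from_coords(coords: np.ndarray, k: int
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-kNN edge list on Pearson row correlations; ties broken by
    node index (stable sort). Returns (edges m x 2 with i<j, weights)."""
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} nuclei, got {n}")
    corr = _row_correlations(coords)
    np.fill_diagonal(corr, -np.inf)
    order = np.argsort(-corr, axis=1, kind="stable")[:, :k]
    neigh = np.zeros((n, n), dtype=bool)
    neigh[np.repeat(np.arange(n), k), order.ravel()] = True
    mutual = neigh & neigh.T
    iu, ju = np.where(np.triu(mutual, 1))
    edges = np.column_stack([iu, ju])
    weights = corr[iu, ju]
    return edges, weights


def build_mknn_graph(embedding: Embedding, k: int = 40) -> SimilarityGraph:
    edges, weights = build_mknn_graph_from_coords(embedding.coords, k)
    return SimilarityGraph(ids=list(embedding.ids), edges=edges,
                           weights=weights, k=k)


def prune_small_components(graph: SimilarityGraph, min_size: int = 30
                           ) -> tuple[SimilarityGraph, list[str]]:
    """Drop connected components with ``min_size`` nodes or fewer (strictly
    larger components are kept)."""
    g = ig.Graph(n=graph.n_nodes, edges=[tuple(e) for e in graph.edges])
    comp = np.array(g.connected_components().membership)
    sizes = np.bincount(comp)
    keep_comp = np.where(sizes > min_size)[0]
    keep_mask = np.isin(comp, keep_comp)
    discarded = [i for i, m in zip(graph.ids, keep_mask) if not m]
    if not discarded:
        return graph, []
    old_to_new = -np.ones(graph.n_nodes, dtype=int)
    old_to_new[keep_mask] = np.arange(int(keep_mask.sum()))
    emask = keep_mask[graph.edges[:, 0]] & keep_mask[graph.edges[:, 1]]
    new_edges = old_to_new[graph.edges[emask]]
    return SimilarityGraph(
        ids=[i for i, m in zip(graph.ids, keep_mask) if m],
        edges=new_edges, weights=graph.weights[emask], k=graph.k,
    ), discarded


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def louvain_labels(n_nodes: int, edges: np.ndarray, weights: np.ndarray,
                   resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain community labels (negative weights clipped to 0 for
    modularity; topology unchanged). Deterministic under a fixed seed."""
    g = ig.Graph(n=n_nodes, edges=[tuple(e) for e in edges])
    w = list(np.clip(weights, 0.0, None))
    ig.set_random_number_generator(_pyrandom.Random(seed))
    part = g.community_multilevel(weights=w, resolution=resolution)
    ig.set_random_number_generator(_pyrandom)
    return np.array(part.membership)


def louvain_partition(graph: SimilarityGraph, resolution: float = 1.0,
                      seed: int = 0) -> ClusterPartition:
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    membership = louvain_labels(graph.n_nodes, graph.edges, graph.weights,
                                resolution=resolution, seed=seed)
    g = graph.to_igraph()
    mod = g.modularity(list(membership), weights="weight")
    labels = np.array([f"C{m:02d}" for m in membership], dtype=object)
    return ClusterPartition(ids=list(graph.ids), labels=labels,
                            modularity=float(mod))


# ---------------------------------------------------------------------------
# Differential expression and markers
# ---------------------------------------------------------------------------

def _resolve_group(norm: NormalizedMatrix, partition: ClusterPartition | None,
                   group) -> np.ndarray:
    pos = {b: i for i, b in enumerate(norm.barcodes)}
    if isinstance(group, str):
        if partition is None:
            raise ValueError("cluster name given but no partition")
        barcodes = partition.members(group)
    else:
        barcodes = list(group)
    idx = np.array([pos[b] for b in barcodes], dtype=int)
    return idx


def differential_expression(norm: NormalizedMatrix,
                            partition: ClusterPartition | None,
                            groupA, groupB, fc: float = 1.5,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test per gene between two nucleus groups on log-normalized
    values, BH-corrected across all tested genes.

    log2FC is computed from expm1-averaged group means:
    log2((mean(2^x - 1) + 1) / (mean(2^x - 1) + 1)). Groups may be cluster
    names (resolved through ``partition``) or explicit barcode lists; they
    must not overlap. The returned table covers every gene with a
    ``significant`` flag for |log2FC| >= log2(fc) and q <= alpha.
    """
    ia = _resolve_group(norm, partition, groupA)
    ib = _resolve_group(norm, partition, groupB)
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both groups need at least 3 nuclei")
    if set(ia) & set(ib):
        raise ValueError("groups overlap")
    A, B = norm.values[:, ia], norm.values[:, ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    mA = np.expm1(A * np.log(2)).mean(axis=1)  # mean of 2^x - 1
    mB = np.expm1(B * np.log(2)).mean(axis=1)
    log2fc = np.log2(mA + 1.0) - np.log2(mB + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    nameA = groupA if isinstance(groupA, str) else "groupA"
    nameB = groupB if isinstance(groupB, str) else "groupB"
    table = pd.DataFrame({
        "gene": norm.genes,
        "log2FC": log2fc,
        "p": p,
        "q": q,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "comparison": f"{nameA}_vs_{nameB}",
    })
    table["significant"] = (np.abs(log2fc) >= np.log2(fc)) & (q <= alpha)
    return table


def count_degs(norm: NormalizedMatrix, partition: ClusterPartition,
               a: str, b: str, fc: float = 1.5, alpha: float = 0.05) -> int:
    return int(differential_expression(norm, partition, a, b, fc, alpha)
               ["significant"].sum())


def refine_partition(partition: ClusterPartition, norm: NormalizedMatrix,
                     min_degs: int = 5, graph: SimilarityGraph | None = None,
                     fc: float = 1.5, alpha: float = 0.05,
                     min_cells: int = 3) -> ClusterPartition:
    """Merge-only refinement of a Louvain partition.

    Repeatedly merge the cluster pair with the fewest genes passing
    FC >= fc and q <= alpha between them, while that count is below
    ``min_degs``; when a graph is supplied only pairs connected by at least
    one inter-cluster edge are candidates. Always merging the globally
    smallest pair (tie by cluster-name order) makes the fixed point
    independent of scan order. Every merge is logged.
    """
    labels = np.array([str(l) for l in partition.labels], dtype=object)
    merge_log = list(partition.merge_log)

    def adjacent_pairs() -> list[tuple[str, str]]:
        names = sorted(set(labels))
        if graph is None:
            return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        lab_of = dict(zip(partition.ids, labels))
        seen = set()
        for (u, v) in graph.edges:
            a, b = lab_of[graph.ids[u]], lab_of[graph.ids[v]]
            if a != b:
                seen.add(tuple(sorted((a, b))))
        return sorted(seen)

    while True:
        best: tuple[int, str, str] | None = None
        part = ClusterPartition(list(partition.ids), labels)
        for a, b in adjacent_pairs():
            na, nb = int((labels == a).sum()), int((labels == b).sum())
            if na < min_cells or nb < min_cells:
                n = -1  # undersized clusters merge unconditionally
            else:
                n = count_degs(norm, part, a, b, fc, alpha)
            if n < min_degs and (best is None or (n, a, b) < best):
                best = (n, a, b)
        if best is None:
            break
        n, a, b = best
        merged = min(a, b)
        other = max(a, b)
        labels[labels == other] = merged
        merge_log.append(f"merged {other} into {merged} ({n} DEGs)")
        logger.info(merge_log[-1])
    return ClusterPartition(list(partition.ids), labels,
                            list(partition.lineage_order),
                            partition.modularity, merge_log)


def rank_markers(norm: NormalizedMatrix, partition: ClusterPartition,
                 top_m: int = 10, fc: float = 1.5,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Cluster markers: highly ranked up-regulated DEGs of the query cluster
    against every other cluster; a gene's aggregate rank is its *worst*
    (max) rank across comparisons, ascending."""
    names = partition.cluster_names()
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    n_genes = len(norm.genes)
    rows = []
    cache: dict[tuple[str, str], pd.DataFrame] = {}

    def table(a: str, b: str) -> pd.DataFrame:
        if (a, b) not in cache:
            t = differential_expression(norm, partition, a, b, fc, alpha)
            cache[(a, b)] = t
            t_rev = t.copy()
            t_rev["log2FC"] = -t["log2FC"]
            t_rev["direction"] = np.where(t_rev["log2FC"] >= 0, "up", "down")
            t_rev["significant"] = (np.abs(t_rev["log2FC"]) >= np.log2(fc)) \
                & (t_rev["q"] <= alpha)
            cache[(b, a)] = t_rev
        return cache[(a, b)]

    for query in names:
        agg = np.zeros(n_genes, dtype=int)
        for other in names:
            if other == query:
                continue
            t = table(query, other)
            up = (t["significant"] & (t["log2FC"] > 0)).to_numpy()
            order = np.lexsort((t["gene"].to_numpy(), -t["log2FC"].to_numpy(),
                                t["q"].to_numpy()))
            rank = np.full(n_genes, n_genes + 1, dtype=int)
            r = 1
            for gi in order:
                if up[gi]:
                    rank[gi] = r
                    r += 1
            agg = np.maximum(agg, rank)
        order = sorted(range(n_genes), key=lambda i: (agg[i], norm.genes[i]))
        for r, gi in enumerate(order[:top_m], start=1):
            if agg[gi] > n_genes:
                break
            rows.append((query, norm.genes[gi], r, int(agg[gi])))
    return pd.DataFrame(rows, columns=["cluster", "gene", "rank", "max_pairwise_rank"])
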