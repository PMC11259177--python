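"""Nucleus/feature quality control, doublet scoring, scran-style
size-factor normalization and highly-variable-gene selection.

The QC rules follow the snRNA-seq conventions for birthdated-cohort data:
nuclei with fewer than 1000 detected features, more than 1% mitochondrial
counts, robust multivariate outliers (low library size, low features, high
Mt fraction) or doublet flags are removed; features must carry more than 20
molecules and be detected in more than 1% and fewer than 80% of the
remaining nuclei, with a sex/stress blacklist taken out. Normalization is
pooled per quick-cluster (median ratio to the cluster pseudo-bulk), rescaled
across clusters, followed by log2(x / sf + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .io import CountMatrix
from .simulate import DEFAULT_BLACKLIST

logger = logging.getLogger(__name__)

MITO_PREFIX = "mt-"


@dataclass
class QCMetrics:
    """Per-nucleus QC metrics plus removal flags (no filtering implied)."""

    table: pd.DataFrame  # barcode, library_size, n_features, mito_fraction, doublet_score
    flags: dict[str, set[str]] = field(default_factory=dict)  # flag -> barcodes


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1) values with the factors that made them."""

    values: np.ndarray            # genes x nuclei, dense float
    genes: list[str]
    barcodes: list[str]
    size_factors: np.ndarray      # per nucleus, mean 1
    hvg_set: list[str] = field(default_factory=list)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def subset_genes(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return self.values[[pos[g] for g in genes]]

    def restrict_genes(self, genes: list[str]) -> "NormalizedMatrix":
        return NormalizedMatrix(self.subset_genes(genes), list(genes),
                                list(self.barcodes), self.size_factors,
                                [g for g in self.hvg_set if g in set(genes)])

    def subset_barcodes(self, barcodes: list[str]) -> "NormalizedMatrix":
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = [pos[b] for b in barcodes]
        return NormalizedMatrix(self.values[:, idx], list(self.genes),
                                list(barcodes), self.size_factors[idx],
                                list(self.hvg_set))


def mito_gene_ids(genes: list[str], prefix: str = MITO_PREFIX) -> list[str]:
    return [g for g in genes if g.startswith(prefix)]


def compute_qc_metrics(counts: CountMatrix,
                       mito_genes: list[str] | None = None) -> QCMetrics:
    """Library size, detected features and Mt fraction per nucleus.

    An all-zero nucleus gets mito_fraction 0 by convention. Unknown mito
    gene ids are ignored with a warning.
    """
    if mito_genes is None:
        mito_genes = mito_gene_ids(counts.genes)
    known = set(counts.genes)
    unknown = [g for g in mito_genes if g not in known]
    if unknown:
        logger.warning("ignoring %d unknown mito gene ids (e.g. %r)",
                       len(unknown), unknown[0])
    mito_genes = [g for g in mito_genes if g in known]
    mat = counts.matrix
    lib = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    nfeat = np.asarray((mat > 0).sum(axis=0)).ravel()
    if mito_genes:
        pos = {g: i for i, g in enumerate(counts.genes)}
        midx = [pos[g] for g in mito_genes]
        msum = np.asarray(mat[midx].sum(axis=0)).ravel().astype(float)
    else:
        msum = np.zeros_like(lib)
    with np.errstate(invalid="ignore", divide="ignore"):
        mfrac = np.where(lib > 0, msum / np.maximum(lib, 1e-300), 0.0)
    table = pd.DataFrame({
        "barcode": counts.barcodes,
        "library_size": lib,
        "n_features": nfeat,
        "mito_fraction": mfrac,
        "doublet_score": np.nan,
    })
    return QCMetrics(table=table)


def _log_libnorm(mat: np.ndarray) -> np.ndarray:
    lib = mat.sum(axis=0)
    lib = np.where(lib > 0, lib, 1.0)
    return np.log1p(mat / lib * np.median(lib))


def detect_doublets(counts: CountMatrix, k: int = 20,
                    n_artificial: int | None = None, seed: int = 0,
                    n_pcs: int = 10) -> np.ndarray:
    """Artificial-doublet kNN score per nucleus.

    Synthesizes ``n_artificial`` artificial doublets (column sums of random
    nucleus pairs; default as many as there are nuclei), co-embeds real and
    artificial profiles in PC space of log library-normalized counts, and
    scores each real nucleus by the fraction of its k nearest neighbors that
    are artificial. Higher = more doublet-like.
    """
    n = counts.n_nuclei
    if n < 4:
        raise ValueError("need at least 4 nuclei for doublet detection")
    if n_artificial is None:
        n_artificial = n
    if n_artificial < 1:
        raise ValueError("n_artificial must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    mat = counts.matrix.toarray().astype(float)
    pairs = np.column_stack([rng.integers(0, n, n_artificial),
                             rng.integers(0, n, n_artificial)])
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 1] + 1) % n
    art = mat[:, pairs[:, 0]] + mat[:, pairs[:, 1]]
    joint = _log_libnorm(np.column_stack([mat, art]))
    d = min(n_pcs, joint.shape[1] - 1, joint.shape[0])
    pcs = PCA(n_components=d, svd_solver="randomized",
              random_state=0).fit_transform(joint.T)
    from sklearn.neighbors import NearestNeighbors
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    neigh = idx[:, 1:]  # drop self
    return (neigh >= n).mean(axis=1)


def doublet_flag(scores: np.ndarray, n_real: int, n_artificial: int,
                 threshold_mult: float = 2.0) -> np.ndarray:
    """Flag nuclei whose score exceeds ``threshold_mult`` times the
    chance-level artificial-neighbor fraction."""
    expectation = n_artificial / (n_artificial + n_real)
    return scores >= threshold_mult * expectation


def filter_nuclei(metrics: QCMetrics, min_features: int = 1000,
                  max_mito: float = 0.01, mv_z_cut: float = 3.0,
                  doublet_flags: np.ndarray | None = None,
                  use_mv_outlier: bool = True) -> tuple[list[str], pd.DataFrame]:
    """Apply the nucleus QC rules; returns (kept barcodes, removal table).

    Removal reasons: ``low_features`` (n_features < min_features),
    ``high_mito`` (mito_fraction > max_mito), ``doublet``, and
    ``mv_outlier`` — a robust per-metric z = (x - median)/MAD rule on the
    directional tails (low library size, low features, high Mt), flagged
    when any |z| > mv_z_cut.
    """
    t = metrics.table
    reasons: dict[str, list[str]] = {b: [] for b in t["barcode"]}

    low = t["n_features"] < min_features
    mito = t["mito_fraction"] > max_mito
    for b in t.loc[low, "barcode"]:
        reasons[b].append("low_features")
    for b in t.loc[mito, "barcode"]:
        reasons[b].append("high_mito")
    if doublet_flags is not None:
        for b in t.loc[np.asarray(doublet_flags, bool), "barcode"]:
            reasons[b].append("doublet")
    if use_mv_outlier:
        def robust_z(x: np.ndarray) -> np.ndarray:
            med = np.median(x)
            mad = np.median(np.abs(x - med)) * 1.4826
            if mad == 0:
                return np.zeros_like(x)
            return (x - med) / mad
        z_lib = robust_z(np.log1p(t["library_size"].to_numpy()))
        z_feat = robust_z(np.log1p(t["n_features"].to_numpy(float)))
        z_mito = robust_z(t["mito_fraction"].to_numpy())
        out = (z_lib < -mv_z_cut) | (z_feat < -mv_z_cut) | (z_mito > mv_z_cut)
        for b in t.loc[out, "barcode"]:
            reasons[b].append("mv_outlier")

    removed = pd.DataFrame(
        [(b, ";".join(r)) for b, r in reasons.items() if r],
        columns=["barcode", "reasons"],
    )
    kept = [b for b in t["barcode"] if not reasons[b]]
    assert len(kept) + len(removed) == len(t)
    return kept, removed


def filter_features(counts: CountMatrix, blacklist: list[str] | None = None,
                    min_total: int = 20, min_frac: float = 0.01,
                    max_frac: float = 0.80) -> list[str]:
    """Retain genes with total > min_total, detection fraction strictly
    inside (min_frac, max_frac), and not blacklisted.

    Apply *after* nucleus filtering; the detection fraction refers to the
    filtered nuclei.
    """
    if counts.n_nuclei == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    if blacklist is None:
        blacklist = DEFAULT_BLACKLIST
    black = set(blacklist)
    total = np.asarray(counts.matrix.sum(axis=1)).ravel()
    frac = np.asarray((counts.matrix > 0).sum(axis=1)).ravel() / counts.n_nuclei
    keep = (total > min_total) & (frac > min_frac) & (frac < max_frac)
    return [g for g, k in zip(counts.genes, keep) if k and g not in black]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _quick_cluster(mat: np.ndarray, k: int = 10, min_size: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Coarse clustering for pooled normalization: Louvain on a mutual-kNN
    graph of rank-transformed profiles; clusters under ``min_size`` are
    merged into their most similar larger neighbor."""
    from .clustering import build_mknn_graph_from_coords, louvain_labels

    n = mat.shape[1]
    if n <= min_size:
        return np.zeros(n, dtype=int)
    ranks = pd.DataFrame(mat).rank(axis=0).to_numpy().T  # nuclei x genes
    d = min(20, n - 1, ranks.shape[1])
    pcs = PCA(n_components=d, svd_solver="randomized",
              random_state=0).fit_transform(ranks - ranks.mean(axis=0))
    k_eff = min(k, n - 1)
    edges, weights = build_mknn_graph_from_coords(pcs, k_eff)
    labels = louvain_labels(n, edges, weights, resolution=1.0, seed=seed)
    # merge undersized clusters into the nearest (centroid-correlation) big one
    labs, counts_ = np.unique(labels, return_counts=True)
    big = [l for l, c in zip(labs, counts_) if c >= min_size]
    if not big:
        return np.zeros(n, dtype=int)
    centroids = {l: pcs[labels == l].mean(axis=0) for l in labs}
    for l, c in zip(labs, counts_):
        if c < min_size:
            tgt = min(big, key=lambda b: np.linalg.norm(centroids[l] - centroids[b]))
            labels[labels == l] = tgt
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def normalize(counts: CountMatrix, batch_labels: list[str] | None = None,
              quick_k: int = 10, min_cluster: int = 50,
              seed: int = 0) -> NormalizedMatrix:
    """Pooled size-factor normalization and log2(x/sf + 1) transform.

    Within each batch, a quick clustering groups similar nuclei; size
    factors are median count ratios to the cluster pseudo-bulk, rescaled
    across clusters (via each cluster's pseudo-bulk ratio to the first
    cluster) so factors are comparable, then globally rescaled to mean 1.
    """
    mat = counts.matrix.toarray().astype(float)
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.barcodes[int(np.argmin(lib))]
        raise ValueError(f"nucleus {bad!r} has zero library size; filter first")
    n = mat.shape[1]
    if batch_labels is None:
        batch_labels = ["all"] * n
    batch_labels = list(map(str, batch_labels))

    sf = np.empty(n)
    for batch in sorted(set(batch_labels)):
        cols = np.array([i for i, b in enumerate(batch_labels) if b == batch])
        sub = mat[:, cols]
        labels = _quick_cluster(sub, k=quick_k, min_size=min_cluster, seed=seed)
        refs: dict[int, np.ndarray] = {}
        sf_b = np.empty(len(cols))
        for l in np.unique(labels):
            members = labels == l
            ref = sub[:, members].mean(axis=1)
            refs[l] = ref
            use = ref > 0
            ratios = sub[np.ix_(use, members)] / ref[use, None]
            f = np.median(ratios, axis=0)
            f = np.where(f > 0, f, np.min(f[f > 0]) if np.any(f > 0) else 1.0)
            sf_b[members] = f
        # cross-cluster rescale: bring every cluster's pseudo-bulk onto the
        # scale of cluster 0 by the median ratio of shared expressed genes
        l0 = np.unique(labels)[0]
        for l in np.unique(labels):
            if l == l0:
                continue
            use = (refs[l0] > 0) & (refs[l] > 0)
            scale = np.median(refs[l][use] / refs[l0][use]) if use.any() else 1.0
            sf_b[labels == l] *= scale
        sf[cols] = sf_b
    sf = sf / sf.mean()
    values = np.log2(mat / sf + 1.0)
    return NormalizedMatrix(values=values, genes=list(counts.genes),
                            barcodes=list(counts.barcodes), size_factors=sf)


def select_hvgs(norm: NormalizedMatrix, n: int = 3000,
                span: float = 0.3) -> list[str]:
    """Top-n genes by biological variance over a mean-variance trend.

    The trend is a lowess fit of per-gene variance against mean of the
    log-expression values; biological variance = total - trend. Ties are
    broken by gene id so the ordering is fully reproducible.
    """
    means = norm.values.mean(axis=1)
    variances = norm.values.var(axis=1, ddof=1)
    if len(means) < 5:
        trend = np.full_like(means, variances.mean())
    else:
        fit = sm.nonparametric.lowess(variances, means, frac=span,
                                      return_sorted=False)
        trend = np.maximum(fit, 0.0)
    bio = variances - trend
    bio[variances == 0] = -np.inf  # a constant gene is never variable
    order = sorted(range(len(means)), key=lambda i: (-bio[i], norm.genes[i]))
    if n > len(order):
        logger.warning("requested %d HVGs but only %d genes; returning all",
                       n, len(order))
        n = len(order)
    return [norm.genes[i] for i in order[:n]]
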