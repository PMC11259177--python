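"""Batch correction by mutual nearest neighbors in PC space and kNN label
transfer from a reference to a query dataset.

The two datasets are assumed to share an embedding dimensionality. Mutual
nearest-neighbor (MNN) pairs are found across batches on centered,
cosine-normalized coordinates; each pair contributes a correction vector
(reference minus query, in the raw space) and every query nucleus is
shifted by a Gaussian-kernel-weighted average of pair vectors. Labels are
then transferred by plurality vote among the k reference neighbors of each
corrected query nucleus, with the vote fraction as confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class CorrectionModel:
    mnn_pairs: np.ndarray          # m x 2 (ref index, query index)
    correction_vectors: np.ndarray  # per query nucleus, d-dim displacement
    kernel_sigma: float


@dataclass
class LabelTransferResult:
    table: pd.DataFrame  # query_id(optional), label, confidence, unassigned

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(object)


def _cosine_normalize(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.where(norms > 0, norms, 1.0)


def find_mnn_pairs(ref: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Cross-batch mutual kNN pairs on centered cosine-normalized coords."""
    center = np.vstack([ref, query]).mean(axis=0)
    r = _cosine_normalize(ref - center)
    q = _cosine_normalize(query - center)
    k_rq = min(k, len(ref))
    k_qr = min(k, len(query))
    nn_r = NearestNeighbors(n_neighbors=k_rq).fit(r)
    nn_q = NearestNeighbors(n_neighbors=k_qr).fit(q)
    _, q_to_r = nn_r.kneighbors(q)   # for each query, its ref neighbors
    _, r_to_q = nn_q.kneighbors(r)   # for each ref, its query neighbors
    ref_neigh = [set(row) for row in r_to_q]
    pairs = [(ri, qi) for qi in range(len(query)) for ri in q_to_r[qi]
             if qi in ref_neigh[ri]]
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def _mnn_correct_once(ref: np.ndarray, query: np.ndarray, k: int,
                      sigma: float | None) -> tuple[np.ndarray, CorrectionModel]:

    pairs = find_mnn_pairs(ref, query, k)
    if len(pairs) == 0:
        raise ValueError("batches share no neighbors (no MNN pairs)")
    vectors = ref[pairs[:, 0]] - query[pairs[:, 1]]

    center = np.vstack([ref, query]).mean(axis=0)
    rn = _cosine_normalize(ref - center)
    qn = _cosine_normalize(query - center)
    anchors = 0.5 * (rn[pairs[:, 0]] + qn[pairs[:, 1]])
    d = np.linalg.norm(qn[:, None, :] - anchors[None, :, :], axis=2)
    if sigma is None:
        sigma = float(np.median(d))
    sig = max(sigma, 1e-12)
    w = np.exp(-0.5 * (d / sig) ** 2)
    wsum = w.sum(axis=1, keepdims=True)
    w = np.where(wsum > 0, w / np.where(wsum > 0, wsum, 1.0), 1.0 / len(pairs))
    corrections = w @ vectors
    model = CorrectionModel(mnn_pairs=pairs, correction_vectors=corrections,
                            kernel_sigma=sig)
    return query + corrections, model


def mnn_correct(ref_embedding: np.ndarray, query_embedding: np.ndarray,
                k: int = 20, sigma: float | None = None,
                max_iter: int = 8, tol: float = 0.01
                ) -> tuple[np.ndarray, CorrectionModel]:
    """Shift the query batch onto the reference in PC space.

    Pair vectors are ref - query in the raw coordinates; each query nucleus
    is corrected by the Gaussian-kernel-weighted mean of pair vectors, with
    distances measured in the centered cosine-normalized space to each
    pair's midpoint (so for identical batches the symmetric pairs cancel
    and the correction is exactly zero). ``sigma`` defaults to the median
    query-to-pair distance. A single pass underestimates large batch
    shifts (pair selection is biased toward the facing edges of the two
    clouds), so passes are repeated with pairs recomputed in between until
    the incremental displacement falls below ``tol`` of the first pass (at
    most ``max_iter`` passes). The returned model accumulates the total
    displacement and keeps the last pass's pairs.
    """
    ref = np.asarray(ref_embedding, float)
    query = np.asarray(query_embedding, float)
    if ref.shape[1] != query.shape[1]:
        raise ValueError("embeddings must share dimensionality")
    corrected = query
    total = np.zeros_like(query)
    model = None
    first_step = None
    for _ in range(max(max_iter, 1)):
        corrected, model = _mnn_correct_once(ref, corrected, k, sigma)
        total += model.correction_vectors
        step = float(np.mean(np.linalg.norm(model.correction_vectors, axis=1)))
        if first_step is None:
            first_step = step
        if first_step == 0 or step < tol * first_step:
            break
    model = CorrectionModel(mnn_pairs=model.mnn_pairs,
                            correction_vectors=total,
                            kernel_sigma=model.kernel_sigma)
    return corrected, model


def transfer_labels(ref_coords: np.ndarray, ref_labels,
                    query_coords: np.ndarray, k: int = 20,
                    min_conf: float = 0.5,
                    min_label_n: int = 10) -> LabelTransferResult:
    """kNN plurality-vote label transfer in the shared (corrected) space.

    Confidence is the plurality fraction of the k reference neighbors;
    ties break toward the label with the smaller aggregate neighbor
    distance. Queries below ``min_conf`` are unassigned, as are labels
    transferred to fewer than ``min_label_n`` queries (rare imputed
    populations are dropped rather than trusted).
    """
    ref = np.asarray(ref_coords, float)
    query = np.asarray(query_coords, float)
    labels = np.asarray(list(ref_labels), dtype=object)
    if k > len(ref):
        raise ValueError(f"k={k} exceeds reference size {len(ref)}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(query)
    out_label, out_conf = [], []
    for i in range(len(query)):
        neigh = labels[idx[i]]
        cands = {}
        for j, l in enumerate(neigh):
            cnt, dsum = cands.get(l, (0, 0.0))
            cands[l] = (cnt + 1, dsum + dist[i, j])
        best = min(cands.items(), key=lambda kv: (-kv[1][0], kv[1][1], str(kv[0])))
        out_label.append(best[0])
        out_conf.append(best[1][0] / k)
    table = pd.DataFrame({"label": out_label, "confidence": out_conf})
    table["unassigned"] = table["confidence"] < min_conf
    counts = table.loc[~table["unassigned"], "label"].value_counts()
    rare = set(counts[counts < min_label_n].index)
    if rare:
        logger.info("dropping rare transferred labels: %s", sorted(rare))
        table.loc[table["label"].isin(rare), "unassigned"] = True
    table.loc[table["unassigned"], "label"] = pd.NA
    return LabelTransferResult(table=table)
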