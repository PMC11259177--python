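"""Regulon activity (recovery-curve AUC), peak-window nucleus groups, and
regulon specificity scores between consecutive states.

A regulon is a TF plus its inferred targets; activity per nucleus is the
area under the recovery curve of the regulon within the top fraction of
that nucleus's expression ranking (AUCell-style, invariant to monotone
transforms of expression). The regulon specificity score between a regulon
r and a nucleus group s is RSS = 1 - sqrt(JSD(P_r, G_s)) with the
Jensen-Shannon divergence in log base 2 (so both lie in [0, 1]), where P_r
is the regulon's activity normalized to sum 1 over nuclei and G_s the
normalized indicator of the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .io import RegulonSet
from .qc import NormalizedMatrix
from .trajectory import PseudotimeAssignment, StateSegmentation

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    values: pd.DataFrame          # regulon x nucleus AUC in [0, 1]
    top_fraction: float = 0.05
    tie_break_seed: int = 0

    def regulons(self) -> list[str]:
        return list(self.values.index)


def infer_coexpression_regulons(norm: NormalizedMatrix, tf_list: list[str],
                                n_top_targets: int = 50, seed: int = 0,
                                min_size: int = 10) -> RegulonSet:
    """Co-expression regulons: per TF, the top ``n_top_targets`` genes by
    Spearman correlation (positive only) across nuclei.

    A simplification of the co-expression stage of regulon inference;
    motif-based pruning is out of scope. TFs absent from the matrix are
    skipped; regulons smaller than ``min_size`` are dropped.
    """
    rs = RegulonSet()
    if not tf_list:
        return rs
    present = set(norm.genes)
    ranks = pd.DataFrame(norm.values.T).rank(axis=0).to_numpy()  # nuclei x genes
    ranks = (ranks - ranks.mean(axis=0))
    sd = ranks.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    ranks = ranks / sd_safe
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    n = ranks.shape[0]
    for tf in tf_list:
        if tf not in present:
            logger.warning("TF %r absent from matrix; skipped", tf)
            continue
        ti = gene_pos[tf]
        if sd[ti] == 0:
            logger.warning("TF %r has constant expression; skipped", tf)
            continue
        rho = ranks.T @ ranks[:, ti] / n
        rho[ti] = -np.inf  # never its own target
        rho[sd == 0] = -np.inf
        order = np.lexsort((np.array(norm.genes, dtype=object), -rho))
        targets = [norm.genes[i] for i in order[:n_top_targets] if rho[i] > 0]
        if len(targets) >= min_size:
            rs.regulons[tf] = targets
            rs.extended[tf] = False
    return rs


# ---------------------------------------------------------------------------
# AUCell-style activity
# ---------------------------------------------------------------------------

def _rankings(expr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-nucleus gene rankings by decreasing expression, ties broken by a
    seeded random permutation (recorded via the caller's seed)."""
    n_genes, n_nuclei = expr.shape
    perm = rng.permutation(n_genes)
    # sort by (-expr, perm): stable argsort of -expr over permuted rows
    shuffled = expr[perm]
    order = np.argsort(-shuffled, axis=0, kind="stable")
    return perm[order]  # gene indices, best-ranked first, per column


def score_activity(norm_or_values, regulons: RegulonSet,
                   top_fraction: float = 0.05, seed: int = 0) -> ActivityMatrix:
    """Recovery-curve AUC of each regulon in each nucleus.

    Genes are ranked per nucleus by decreasing expression; the recovery
    curve counts regulon genes within the top x ranks for x = 1..X,
    X = ceil(top_fraction * G); the AUC is normalized by the maximum
    achievable area (regulon occupying the top ranks). Regulons with no
    measured gene are reported as all-NaN rows.
    """
    if isinstance(norm_or_values, NormalizedMatrix):
        genes, barcodes = norm_or_values.genes, norm_or_values.barcodes
        expr = norm_or_values.values
    else:
        expr, genes, barcodes = norm_or_values
    G = len(genes)
    X = int(np.ceil(top_fraction * G))
    rng = np.random.default_rng(seed)
    rankings = _rankings(np.asarray(expr, float), rng)  # G x n, gene idx
    top = rankings[:X]  # X x n
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows = {}
    for name, targets in regulons.regulons.items():
        idx = {gene_pos[g] for g in targets if g in gene_pos}
        if not idx:
            logger.warning("regulon %r shares no genes with the matrix; "
                           "activity undefined", name)
            rows[name] = np.full(len(barcodes), np.nan)
            continue
        R = len(idx)
        hits = np.isin(top, list(idx))          # X x n boolean
        rec = np.cumsum(hits, axis=0)           # recovery curve per nucleus
        auc = rec.sum(axis=0).astype(float)
        max_auc = float(np.minimum(np.arange(1, X + 1), R).sum())
        rows[name] = auc / max_auc
    values = pd.DataFrame(rows, index=list(barcodes)).T
    return ActivityMatrix(values=values, top_fraction=top_fraction,
                          tie_break_seed=seed)


# ---------------------------------------------------------------------------
# Peak groups and RSS
# ---------------------------------------------------------------------------

def assign_peak_groups(pseudotime: PseudotimeAssignment | pd.DataFrame,
                       segmentation: StateSegmentation) -> pd.Series:
    """Label each nucleus with the index (1-based) of the peak window its
    pseudotime falls into; nuclei outside every window get <NA>.

    Windows must not overlap (peaks closer than the window width raise).
    """
    wins = segmentation.peak_windows
    for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
        if b1 > a2:
            raise ValueError("overlapping peak windows: peaks closer than "
                             "the window width")
    table = pseudotime.table if isinstance(pseudotime, PseudotimeAssignment) \
        else pseudotime
    t = table["t"].to_numpy(float)
    out = np.full(len(t), pd.NA, dtype=object)
    for g, (a, b) in enumerate(wins, start=1):
        out[(t >= a) & (t <= b)] = g
    return pd.Series(out, index=table["barcode"].to_numpy(), name="peak_group")


def compute_rss(activity: ActivityMatrix, groups: pd.Series) -> pd.DataFrame:
    """Regulon specificity score per (regulon, group).

    RSS = 1 - sqrt(JSD(P_r, G_s)) with log-base-2 JSD; computed over the
    grouped nuclei only. All-zero or undefined activity rows are reported
    as NaN.
    """
    grouped = groups.dropna()
    if grouped.nunique() < 2:
        raise ValueError("need at least 2 nucleus groups")
    barcodes = [b for b in activity.values.columns if b in grouped.index]
    act = activity.values[barcodes]
    glabels = grouped.loc[barcodes]
    out = {}
    for s in sorted(glabels.unique()):
        ind = (glabels == s).to_numpy(float)
        G_s = ind / ind.sum()
        col = []
        for r in act.index:
            a = act.loc[r].to_numpy(float)
            tot = np.nansum(a)
            if not np.isfinite(tot) or tot <= 0 or np.any(np.isnan(a)):
                col.append(np.nan)
                continue
            P_r = a / tot
            col.append(1.0 - float(jensenshannon(P_r, G_s, base=2)))
        out[s] = col
    return pd.DataFrame(out, index=list(act.index))


def compare_consecutive_states(rss: pd.DataFrame, activity: ActivityMatrix,
                               groups: pd.Series) -> pd.DataFrame:
    """Rank regulons by activity change between each pair of consecutive
    states.

    For every adjacent state pair (s, s+1): delta RSS, delta mean activity,
    direction (up into s+1 / down out of s), ranked by |delta mean
    activity| then |delta RSS|. Also attaches the z-scored state-mean
    activity of each regulon across states (the heatmap values).
    """
    states = sorted(c for c in rss.columns)
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    grouped = groups.dropna()
    barcodes = [b for b in activity.values.columns if b in grouped.index]
    act = activity.values[barcodes]
    glabels = grouped.loc[barcodes]
    state_mean = pd.DataFrame(
        {s: act.loc[:, (glabels == s).to_numpy()].mean(axis=1) for s in states})
    mu = state_mean.mean(axis=1)
    sd = state_mean.std(axis=1, ddof=0)
    z = state_mean.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    rows = []
    for s1, s2 in zip(states, states[1:]):
        d_act = state_mean[s2] - state_mean[s1]
        d_rss = rss[s2] - rss[s1]
        for r in rss.index:
            rows.append((f"{s1}->{s2}", r, float(d_rss.loc[r]),
                         float(d_act.loc[r]),
                         "up" if d_act.loc[r] > 0 else "down"))
    table = pd.DataFrame(rows, columns=["comparison", "regulon", "delta_rss",
                                        "delta_activity", "direction"])
    table["rank"] = (table.groupby("comparison")["delta_activity"]
                     .transform(lambda x: (-x.abs()).rank(method="first"))
                     .astype(int))
    table = table.sort_values(["comparison", "rank"]).reset_index(drop=True)
    table.attrs["zscore"] = z
    return table
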