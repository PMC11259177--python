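"""Screening transcription factors for pseudotime dependence and ordering
their on/off switching events into a cascade.

Each TF is first tested for association with pseudotime by a likelihood
ratio test of a cubic-spline smooth against a constant fit (BH-corrected
across the TF universe). Significant TFs are then binarized along the
ordered lineage clusters by their per-cluster detection fraction with
hysteresis (expressed at >= on_frac, silent at <= off_frac, carry the
previous state in between); every state change emits a switch event at the
boundary cluster, supporting off-then-on patterns (two events per gene at
most). Events ordered by switching pseudotime form the cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterPartition
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    gene: str
    lrt: float
    df: int
    p: float
    q: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.q < 0.05)


@dataclass
class SwitchEvent:
    gene: str
    direction: str          # on | off
    cluster_at_switch: str
    t_switch: float
    magnitude: float        # |detection-fraction change| at the boundary


def _spline_basis(t: np.ndarray, df_smooth: int) -> np.ndarray:
    """Cubic B-spline design matrix with ``df_smooth`` columns (spanning the
    constant), knots at quantiles of t."""
    k = 3
    n_interior = df_smooth - k - 1
    lo, hi = float(t.min()), float(t.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    return BSpline.design_matrix(t, knots, k).toarray()


def association_test(expr_gene: np.ndarray, t: np.ndarray,
                     df_smooth: int = 4) -> AssociationResult:
    """LRT of a Gaussian cubic-spline smooth over pseudotime vs a constant.

    2*dlogL = n * log(RSS0 / RSS1) ~ chi2(df_smooth - 1). A constant
    expression vector gets p = 1 by convention.
    """
    y = np.asarray(expr_gene, float)
    t = np.asarray(t, float)
    if len(y) < 30:
        raise ValueError("need at least 30 nuclei with defined pseudotime")
    if np.ptp(y) == 0:
        return AssociationResult(gene="", lrt=0.0, df=df_smooth - 1, p=1.0)
    X = _spline_basis(t, df_smooth)
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    if rss1 <= 0 or rss0 <= rss1 * 1e-15:
        lrt = np.inf
    else:
        lrt = n * np.log(rss0 / rss1)
    df = df_smooth - 1
    p = float(scipy.stats.chi2.sf(lrt, df))
    return AssociationResult(gene="", lrt=float(lrt), df=df, p=p)


def screen_tfs(norm: NormalizedMatrix, tf_list: list[str],
               pseudotime: pd.DataFrame, df_smooth: int = 4,
               fdr: float = 0.05) -> pd.DataFrame:
    """Run the association test over a TF universe and BH-correct.

    ``pseudotime`` needs barcode and t columns for the included nuclei; TFs
    absent from the matrix are skipped with a warning. Returns a table
    (gene, lrt, df, p, q, significant).
    """
    present = [g for g in tf_list if g in set(norm.genes)]
    missing = len(tf_list) - len(present)
    if missing:
        logger.warning("%d TFs absent from the matrix; skipped", missing)
    sub = norm.subset_barcodes(list(pseudotime["barcode"]))
    t = pseudotime["t"].to_numpy(float)
    rows = []
    for g in present:
        r = association_test(sub.gene_row(g), t, df_smooth)
        rows.append((g, r.lrt, r.df, r.p))
    table = pd.DataFrame(rows, columns=["gene", "lrt", "df", "p"])
    table["q"] = multipletests(table["p"], method="fdr_bh")[1] if len(table) else []
    table["significant"] = table["q"] < fdr
    return table


# ---------------------------------------------------------------------------
# Switch detection
# ---------------------------------------------------------------------------

def detection_profile(expr_gene: np.ndarray, labels: np.ndarray,
                      lineage_order: list[str], min_nuclei: int = 5
                      ) -> tuple[list[str], np.ndarray]:
    """Per-cluster detection fraction (expr > 0) along lineage order;
    clusters with fewer than ``min_nuclei`` nuclei are excluded (warned)."""
    keep, fracs = [], []
    for c in lineage_order:
        mask = labels == c
        n = int(mask.sum())
        if n < min_nuclei:
            logger.warning("cluster %s has %d nuclei (<%d); excluded from "
                           "switch profile", c, n, min_nuclei)
            continue
        keep.append(c)
        fracs.append(float((np.asarray(expr_gene)[mask] > 0).mean()))
    return keep, np.array(fracs)


def detect_switches(expr_gene: np.ndarray, partition: ClusterPartition,
                    lineage_order: list[str], pseudotime: pd.DataFrame,
                    on_frac: float = 0.25, off_frac: float = 0.10,
                    gene: str = "", min_nuclei: int = 5,
                    normalize_range: bool = True) -> list[SwitchEvent]:
    """Hysteresis binarization of the per-cluster detection profile.

    With ``normalize_range`` (default) the profile is rescaled to its own
    [min, max] range before thresholding, so the call timing does not
    depend on a gene's expression amplitude and weakly-expressed TFs are
    still callable; set it False to threshold raw detection fractions.

    The initial state is 'expressed' iff the first cluster's fraction is
    >= on_frac. Walking along the lineage, the state flips to expressed at
    >= on_frac and to silent at <= off_frac; in between the previous state
    carries. Each flip emits an event at the boundary cluster with
    t_switch = mean pseudotime of the first cluster in the new state. At
    most two events (the largest fraction changes) are kept, supporting
    off-then-on patterns.
    """
    ids = pseudotime["barcode"].to_numpy()
    tmap = dict(zip(ids, pseudotime["t"].to_numpy(float)))
    lab_of = dict(zip(partition.ids, map(str, partition.labels)))
    labels = np.array([lab_of.get(b, "") for b in ids], dtype=object)
    clusters, fracs = detection_profile(expr_gene, labels, lineage_order,
                                        min_nuclei)
    if len(clusters) < 2:
        return []
    if normalize_range:
        span = fracs.max() - fracs.min()
        if span > 0:
            fracs = (fracs - fracs.min()) / span
    mean_t = {c: float(np.mean([tmap[b] for b, l in zip(ids, labels) if l == c]))
              for c in clusters}
    state = fracs[0] >= on_frac
    events: list[SwitchEvent] = []
    for i in range(1, len(clusters)):
        new_state = state
        if fracs[i] >= on_frac:
            new_state = True
        elif fracs[i] <= off_frac:
            new_state = False
        if new_state != state:
            events.append(SwitchEvent(
                gene=gene, direction="on" if new_state else "off",
                cluster_at_switch=clusters[i], t_switch=mean_t[clusters[i]],
                magnitude=abs(float(fracs[i] - fracs[i - 1])),
            ))
        state = new_state
    if len(events) > 2:
        keep = sorted(sorted(events, key=lambda e: -e.magnitude)[:2],
                      key=lambda e: e.t_switch)
        events = keep
    return events


def detect_all_switches(norm: NormalizedMatrix, partition: ClusterPartition,
                        lineage_order: list[str], pseudotime: pd.DataFrame,
                        genes: list[str], on_frac: float = 0.25,
                        off_frac: float = 0.10) -> pd.DataFrame:
    """Switch events for a list of (association-passing) genes as a table."""
    sub = norm.subset_barcodes(list(pseudotime["barcode"]))
    rows = []
    for g in genes:
        for ev in detect_switches(sub.gene_row(g), partition, lineage_order,
                                  pseudotime, on_frac, off_frac, gene=g):
            rows.append((ev.gene, ev.direction, ev.cluster_at_switch,
                         ev.t_switch, ev.magnitude))
    return pd.DataFrame(rows, columns=["gene", "direction",
                                       "cluster_at_switch", "t_switch",
                                       "magnitude"])


def build_cascade(events: pd.DataFrame, norm: NormalizedMatrix | None = None,
                  partition: ClusterPartition | None = None,
                  lineage_order: list[str] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Order switching genes by their first event's pseudotime (ties by
    gene id) and, when expression is supplied, emit the row-normalized
    per-cluster mean expression matrix for heatmap plotting."""
    if events.empty:
        raise ValueError("no switch events")
    first = (events.sort_values(["gene", "t_switch"])
             .groupby("gene", as_index=False).first())
    order = first.sort_values(["t_switch", "gene"], kind="stable")
    order = order.reset_index(drop=True)
    order["n_events"] = order["gene"].map(events.groupby("gene").size())
    heat = None
    if norm is not None and partition is not None and lineage_order:
        rows = []
        lab_of = dict(zip(partition.ids, map(str, partition.labels)))
        labels = np.array([lab_of.get(b, "") for b in norm.barcodes], dtype=object)
        for g in order["gene"]:
            expr = norm.gene_row(g)
            means = [expr[labels == c].mean() if (labels == c).any() else 0.0
                     for c in lineage_order]
            m = np.array(means)
            mx = m.max()
            rows.append(m / mx if mx > 0 else m)
        heat = pd.DataFrame(rows, index=list(order["gene"]),
                            columns=lineage_order)
    return order, heat
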