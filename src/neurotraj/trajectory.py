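"""Principal-curve pseudotime, per-cohort densities, and density-valley
state segmentation.

The neuronal-lineage clusters (RGL ... GCmat1) are isolated, a principal
curve is fitted through a 3-dimensional embedding (initialized from the
minimum-spanning-tree path over cluster centroids, then iteratively
projected and smoothed), and arc-length position is rescaled to a [0, 100]
pseudotime axis with the root cluster at 0. Per-cohort Gaussian kernel
densities over pseudotime typically show a small number of modes; local
maxima of the pooled density and the valleys between them partition the
axis into cellular states, and 5-unit windows centered on the peaks define
the nucleus groups used for regulon-specificity comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.csgraph
import scipy.signal
import scipy.spatial.distance

from .clustering import ClusterPartition, Embedding
from .qc import NormalizedMatrix
from .simulate import LINEAGE_ORDER

logger = logging.getLogger(__name__)

#: Pseudotime grid used for all density curves: 0..100 in steps of 0.25.
T_GRID = np.arange(0.0, 100.0 + 1e-9, 0.25)


@dataclass
class PrincipalCurve:
    control_points: np.ndarray      # ordered c x d coordinates
    arc_length: np.ndarray          # cumulative length, strictly increasing
    cluster_path: list[str]         # cluster ids the initial curve traverses
    converged: bool = True
    n_iter: int = 0


@dataclass
class PseudotimeAssignment:
    table: pd.DataFrame  # barcode, t, cohort, included

    def included_t(self) -> pd.DataFrame:
        return self.table[self.table["included"]]


@dataclass
class StateSegmentation:
    peaks: np.ndarray               # ordered t positions of density maxima
    valleys: np.ndarray             # minima between consecutive peaks
    states: list[tuple[float, float]]   # closed-open intervals tiling [0,100]
    peak_windows: list[tuple[float, float]]  # [peak - w/2, peak + w/2]
    grid: np.ndarray = field(default_factory=lambda: T_GRID.copy())
    pooled_density: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# Lineage selection
# ---------------------------------------------------------------------------

def select_lineage(partition: ClusterPartition, norm: NormalizedMatrix,
                   lineage_clusters: list[str] | None = None,
                   ventral_genes: list[str] | None = None,
                   z_cut: float = 2.0,
                   terminal_cluster: str | None = None) -> list[str]:
    """Barcodes of nuclei included in the trajectory fit.

    Drops every nucleus outside ``lineage_clusters`` (default: the
    RGL..GCmat1 lineage order) and, within the terminal cluster, nuclei
    whose mean z-scored ventral-signature expression exceeds ``z_cut`` —
    emulating the exclusion of ventral-identity mature granule cells.
    """
    if lineage_clusters is None:
        lineage_clusters = [c for c in LINEAGE_ORDER
                            if c in set(map(str, partition.labels))]
    keep = [b for b, l in zip(partition.ids, partition.labels)
            if str(l) in set(lineage_clusters)]
    if not ventral_genes:
        if ventral_genes is not None:
            logger.warning("empty ventral gene list; skipping ventral exclusion")
        return keep
    present = [g for g in ventral_genes if g in set(norm.genes)]
    if not present:
        logger.warning("no ventral genes found in matrix; skipping exclusion")
        return keep
    terminal = terminal_cluster or lineage_clusters[-1]
    sub = norm.subset_barcodes(keep)
    expr = sub.subset_genes(present)  # genes x nuclei
    mu = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    score = ((expr - mu) / sd).mean(axis=0)
    lab_of = dict(zip(partition.ids, map(str, partition.labels)))
    out = {b for b, s in zip(keep, score)
           if lab_of[b] == terminal and s > z_cut}
    if out:
        logger.info("excluded %d ventral-high nuclei from %s", len(out), terminal)
    return [b for b in keep if b not in out]


# ---------------------------------------------------------------------------
# Principal curve
# ---------------------------------------------------------------------------

def _project_to_polyline(points: np.ndarray, ctrl: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a piecewise-linear curve.

    Returns (arc-length position, projected coordinates) per point.
    """
    seg = np.diff(ctrl, axis=0)                       # s x d
    seg_len = np.linalg.norm(seg, axis=1)
    seg_len = np.where(seg_len > 0, seg_len, 1e-12)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # pairwise: for each point and segment, clamp the projection parameter
    diff = points[:, None, :] - ctrl[None, :-1, :]    # n x s x d
    tpar = np.einsum("nsd,sd->ns", diff, seg) / (seg_len ** 2)
    tpar = np.clip(tpar, 0.0, 1.0)
    proj = ctrl[None, :-1, :] + tpar[:, :, None] * seg[None, :, :]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(dist2, axis=1)
    n = len(points)
    pos = cum[best] + tpar[np.arange(n), best] * seg_len[best]
    coords = proj[np.arange(n), best]
    return pos, coords


def _smooth_by_order(points: np.ndarray, pos: np.ndarray,
                     span: float, n_ctrl: int = 100) -> np.ndarray:
    """Local-linear smoother of each coordinate against arc-length
    position (degree-1 local regression avoids the endpoint shrinkage a
    plain moving average suffers), down-sampled to ``n_ctrl`` control
    points."""
    import statsmodels.api as sm_api

    order = np.argsort(pos, kind="stable")
    x = pos[order]
    # strictly increasing regressor for stable evaluation
    x = x + np.arange(len(x)) * 1e-9
    sm = np.column_stack([
        sm_api.nonparametric.lowess(points[order, j], x, frac=span, it=0,
                                    return_sorted=False)
        for j in range(points.shape[1])
    ])
    idx = np.linspace(0, len(sm) - 1, min(n_ctrl, len(sm))).astype(int)
    return sm[idx]


def _mst_path(centroids: np.ndarray, names: list[str], root: str) -> list[str]:
    """Path from the root centroid to the farthest leaf of the centroid MST."""
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(centroids))
    mst = scipy.sparse.csgraph.minimum_spanning_tree(d)
    dist, pred = scipy.sparse.csgraph.shortest_path(
        mst, directed=False, return_predecessors=True,
        indices=names.index(root))
    far = int(np.argmax(np.where(np.isinf(dist), -1, dist)))
    path = [far]
    while path[-1] != names.index(root):
        path.append(int(pred[path[-1]]))
    return [names[i] for i in reversed(path)]


def fit_principal_curve(embedding: Embedding | np.ndarray,
                        partition: ClusterPartition,
                        root_cluster: str = "RGL",
                        max_iter: int = 50, tol: float = 1e-3,
                        span: float = 0.2,
                        cohorts: dict[str, float] | None = None
                        ) -> tuple[PrincipalCurve, PseudotimeAssignment]:
    """Fit a principal curve and assign pseudotime in [0, 100].

    The initial curve is the piecewise-linear path through cluster
    centroids along the MST from the root cluster to its farthest leaf;
    iterations alternate projecting nuclei onto the curve and re-smoothing
    the coordinates along projection order until the mean projection
    movement falls below ``tol`` times the embedding scale. Pseudotime is
    rescaled arc length with the root at 0.
    """
    if isinstance(embedding, Embedding):
        coords = embedding.coords
        ids = list(embedding.ids)
    else:
        coords = np.asarray(embedding, float)
        ids = list(partition.ids)
    lab_of = dict(zip(partition.ids, map(str, partition.labels)))
    labels = np.array([lab_of[b] for b in ids], dtype=object)
    names = sorted(set(labels))
    if root_cluster not in names:
        raise ValueError(f"root cluster {root_cluster!r} not present")
    centroids = np.vstack([coords[labels == c].mean(axis=0) for c in names])
    path = _mst_path(centroids, names, root_cluster)
    ctrl = np.vstack([centroids[names.index(c)] for c in path])

    scale = float(np.linalg.norm(coords.std(axis=0)))
    pos, proj = _project_to_polyline(coords, ctrl)
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        ctrl = _smooth_by_order(coords, pos, span)
        new_pos, new_proj = _project_to_polyline(coords, ctrl)
        move = float(np.mean(np.linalg.norm(new_proj - proj, axis=1)))
        pos, proj = new_pos, new_proj
        if move < tol * scale:
            converged = True
            break
    if not converged:
        logger.warning("principal curve did not converge in %d iterations",
                       max_iter)
    # orient so the root cluster sits at low t
    root_mean = pos[labels == root_cluster].mean()
    other = pos[labels != root_cluster]
    if other.size and root_mean > other.mean():
        pos = pos.max() - pos
    rng_span = pos.max() - pos.min()
    t = (pos - pos.min()) / (rng_span if rng_span > 0 else 1.0) * 100.0

    seg_len = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.maximum(seg_len, 1e-12))])
    curve = PrincipalCurve(control_points=ctrl, arc_length=arc,
                           cluster_path=path, converged=converged, n_iter=it)
    table = pd.DataFrame({
        "barcode": ids,
        "t": t,
        "cohort": [cohorts.get(b, np.nan) if cohorts else np.nan for b in ids],
        "included": True,
    })
    return curve, PseudotimeAssignment(table)


# ---------------------------------------------------------------------------
# Densities and state segmentation
# ---------------------------------------------------------------------------

def _kde(t: np.ndarray, grid: np.ndarray, min_bw: float = 1.0) -> np.ndarray:
    """Gaussian KDE with Silverman bandwidth, floored at ``min_bw`` t-units
    (handles point masses), normalized to integrate to 1 on the grid."""
    t = np.asarray(t, float)
    n = len(t)
    sd = t.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(t, [75, 25])) if n > 1 else 0.0
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = max(0.9 * spread * n ** (-0.2) if spread > 0 else 0.0, min_bw)
    z = (grid[None, :] - t[:, None]) / bw
    dens = np.exp(-0.5 * z ** 2).sum(axis=0) / (n * bw * np.sqrt(2 * np.pi))
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def cohort_density(pseudotime: PseudotimeAssignment, bandwidth: float | None = None,
                   min_per_cohort: int = 10, grid: np.ndarray = T_GRID
                   ) -> pd.DataFrame:
    """Per-cohort and pooled KDE curves over the pseudotime grid.

    Returns a tidy frame with columns t, cohort ('pooled' for the overall
    curve) and density; every curve integrates to 1.
    """
    inc = pseudotime.included_t()
    frames = []
    for cohort, grp in inc.groupby("cohort", dropna=True):
        if len(grp) < min_per_cohort:
            logger.warning("cohort %s has %d nuclei (<%d); skipped",
                           cohort, len(grp), min_per_cohort)
            continue
        dens = (_kde(grp["t"].to_numpy(), grid) if bandwidth is None else
                _kde_fixed(grp["t"].to_numpy(), grid, bandwidth))
        frames.append(pd.DataFrame({"t": grid, "cohort": str(cohort),
                                    "density": dens}))
    pooled = (_kde(inc["t"].to_numpy(), grid) if bandwidth is None else
              _kde_fixed(inc["t"].to_numpy(), grid, bandwidth))
    frames.append(pd.DataFrame({"t": grid, "cohort": "pooled",
                                "density": pooled}))
    return pd.concat(frames, ignore_index=True)


def _kde_fixed(t: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[None, :] - np.asarray(t, float)[:, None]) / bw
    dens = np.exp(-0.5 * z ** 2).sum(axis=0) / (len(t) * bw * np.sqrt(2 * np.pi))
    return dens / np.trapezoid(dens, grid)


def segment_states(pooled_density: np.ndarray, grid: np.ndarray = T_GRID,
                   min_prominence: float = 0.05,
                   window: float = 5.0) -> StateSegmentation:
    """Segment pseudotime at density valleys.

    Local maxima with prominence >= ``min_prominence`` (as a fraction of the
    maximum density) become peaks; the argmin between consecutive peaks is a
    valley and a state boundary; states tile [0, 100] as closed-open
    intervals; ``peak_windows`` are [p - window/2, p + window/2].
    """
    dens = np.asarray(pooled_density, float)
    if dens.max() <= 0:
        raise ValueError("degenerate density: no mass")
    idx, _ = scipy.signal.find_peaks(dens, prominence=min_prominence * dens.max())
    if len(idx) == 0:
        raise ValueError("degenerate density: no peaks")
    peaks = grid[idx]
    valleys = []
    for a, b in zip(idx, idx[1:]):
        valleys.append(grid[a + int(np.argmin(dens[a:b + 1]))])
    valleys = np.array(valleys)
    bounds = [grid[0], *valleys, grid[-1]]
    states = [(float(a), float(b)) for a, b in zip(bounds, bounds[1:])]
    windows = [(float(p - window / 2), float(p + window / 2)) for p in peaks]
    return StateSegmentation(peaks=peaks, valleys=valleys, states=states,
                             peak_windows=windows, grid=grid.copy(),
                             pooled_density=dens)
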