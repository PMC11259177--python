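"""Synthetic birthdated-cohort snRNA-seq generator with planted ground truth.

The generator emulates the structure of a birthdating experiment in the adult
dentate gyrus: cohorts of nuclei labeled at one induction time and sampled at
a known age, drawn from a single developmental trajectory (RGL -> NPC -> NB ->
GCimm -> GCyoung -> GCmat1) plus off-trajectory glial clusters. Every nucleus
carries a latent pseudotime t in [0, 100]; gene expression follows per-gene
mean curves over t (sigmoid TF switches, effector ramps, a cell-cycle bump
confined to the progenitor interval, constant housekeeping / mitochondrial /
sex-stress-like genes) and counts are negative-binomial with per-gene
dispersion and log-normal per-nucleus library-size factors.

Ground truth (per-nucleus t, cluster, state, artifact flags; per-gene class,
switch time, direction, regulon membership) is emitted alongside the counts so
every downstream stage can be verified by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, RegulonSet

# ---------------------------------------------------------------------------
# Fixed lineage layout of the simulation.
#
# Pseudotime is scaled to [0, 100]. Clusters tile the axis in lineage order;
# the three state boundaries sit in the valleys between the four density
# modes of the default cohort designs (quiescent stem cells, proliferative
# progenitors, immature neurons, young/mature neurons).
# ---------------------------------------------------------------------------

LINEAGE_ORDER: list[str] = [
    "RGL", "NPC", "NB1", "NB2", "GCimm1", "GCimm2", "GCyoung", "GCmat1",
]

CLUSTER_INTERVALS: dict[str, tuple[float, float]] = {
    "RGL": (0.0, 20.0),
    "NPC": (20.0, 42.0),
    "NB1": (42.0, 49.0),
    "NB2": (49.0, 54.0),
    "GCimm1": (54.0, 63.0),
    "GCimm2": (63.0, 72.0),
    "GCyoung": (72.0, 86.0),
    "GCmat1": (86.0, 100.0),
}

GLIAL_CLUSTERS: list[str] = ["Astro", "OPC", "Oligo", "Peri"]

#: Valleys between the four planted density modes; states are the intervals
#: [0,20), [20,42), [42,72), [72,100].
STATE_BOUNDARIES: list[float] = [20.0, 42.0, 72.0]

#: Sex/stress genes removed during feature QC (shipped default, editable).
DEFAULT_BLACKLIST: list[str] = [
    "Ehd2", "Espl1", "Jarid1d", "Pnpla4", "Rps4y1", "Xist", "Tsix",
    "Eif2s3y", "Ddx3y", "Uty", "Kdm5d", "Rpl26", "Gstp1", "Rpl35a",
    "Erh", "Slc25a5", "Pgk1", "Eno1", "Tubb2a", "Emc4", "Scg5",
]

GENE_CLASSES = (
    "tf_switch", "effector_ramp", "cellcycle", "housekeeping",
    "glial", "mito", "blacklist_like",
)

#: Classes whose mean curve does not depend on pseudotime; off-trajectory
#: (glial) nuclei express only these plus their own cluster's glial genes.
_CONSTANT_CLASSES = frozenset({"housekeeping", "mito", "blacklist_like"})

#: Logistic scale so a switch runs 10% -> 90% in about 8 pseudotime units.
SIGMOID_SCALE = 1.8


def true_state_of(t: float | np.ndarray) -> np.ndarray:
    """Map pseudotime to the planted cellular state 1..4 (0 for NaN)."""
    t = np.asarray(t, dtype=float)
    state = np.searchsorted(STATE_BOUNDARIES, t, side="right") + 1
    return np.where(np.isnan(t), 0, state).astype(int)


def true_cluster_of(t: np.ndarray) -> np.ndarray:
    """Map pseudotime to the planted lineage cluster label."""
    bounds = [CLUSTER_INTERVALS[c][1] for c in LINEAGE_ORDER[:-1]]
    idx = np.searchsorted(bounds, np.asarray(t, float), side="right")
    return np.array(LINEAGE_ORDER, dtype=object)[idx]


def _sigmoid(t: np.ndarray, t0: float, scale: float = SIGMOID_SCALE) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, float) - t0) / scale))


# ---------------------------------------------------------------------------
# Gene programs
# ---------------------------------------------------------------------------

@dataclass
class GeneProgram:
    """One gene's expected-expression curve over pseudotime plus NB dispersion.

    ``mean_curve`` maps t in [0, 100] to an expected count (arbitrary mean
    units, >= 0). ``baseline`` is what off-trajectory nuclei see for
    trajectory-dependent classes. ``dispersion`` is the NB size parameter
    theta (variance = mu + mu^2/theta); ``np.inf`` means Poisson.
    """

    gene_id: str
    gene_class: str
    mean_curve: Callable[[np.ndarray], np.ndarray]
    dispersion: float = 2.0
    switch_time: float | None = None
    direction: str | None = None  # on | off | on_off_on
    baseline: float = 0.0
    glial_cluster: str | None = None
    regulon: str | None = None  # TF gene id this gene is a planted target of

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")


def _switch_curve(t0: float, direction: str, low: float, high: float,
                  scale: float = SIGMOID_SCALE) -> Callable:
    if direction == "on":
        return lambda t: low + (high - low) * _sigmoid(t, t0, scale)
    if direction == "off":
        return lambda t: low + (high - low) * (1.0 - _sigmoid(t, t0, scale))
    raise ValueError(direction)


def _interval_curve(a: float, b: float, low: float, high: float,
                    scale: float) -> Callable:
    """on_off_on-style indicator bump: high inside [a, b), low outside."""
    return lambda t: low + (high - low) * _sigmoid(t, a, scale) * (1.0 - _sigmoid(t, b, scale))


def make_gene_programs(
    n_genes: int,
    n_tf: int,
    frac_off_switch: float = 0.62,
    seed: int = 0,
    n_regulons: int = 10,
    targets_per_regulon: int = 25,
) -> list[GeneProgram]:
    """Build the default gene-program catalog (the per-gene ground truth).

    ``n_tf`` genes are sigmoid TF switches with switch times uniform on
    (10, 90); exactly ``round(frac_off_switch * n_tf)`` of them switch off,
    the rest on. The remaining genes are split into effector ramps, a
    cell-cycle bump confined to the NPC interval, glial markers, constant
    housekeeping, mitochondrial ('mt-' prefixed) and sex/stress-like
    blacklist genes. The first ``n_regulons`` TFs seed planted regulons whose
    targets (drawn from the effector pool) share the TF's curve shape.

    Deterministic given ``seed``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not (0 <= n_tf <= n_genes):
        raise ValueError("need 0 <= n_tf <= n_genes")
    if not (0.0 <= frac_off_switch <= 1.0):
        raise ValueError("frac_off_switch must be in [0, 1]")

    rng = np.random.default_rng(seed)
    programs: list[GeneProgram] = []

    # --- TF switches ------------------------------------------------------
    n_off = int(round(frac_off_switch * n_tf))
    directions = np.array(["off"] * n_off + ["on"] * (n_tf - n_off), dtype=object)
    rng.shuffle(directions)
    switch_times = rng.uniform(10.0, 90.0, size=n_tf)
    tf_high = rng.lognormal(np.log(3.0), 0.4, size=n_tf)
    for i in range(n_tf):
        high = float(tf_high[i])
        low = 0.02 * high
        programs.append(GeneProgram(
            gene_id=f"Tf{i:04d}",
            gene_class="tf_switch",
            mean_curve=_switch_curve(float(switch_times[i]), str(directions[i]),
                                     low, high),
            dispersion=2.0,
            switch_time=float(switch_times[i]),
            direction=str(directions[i]),
            baseline=low,
        ))

    # --- split the remaining genes ---------------------------------------
    n_rest = n_genes - n_tf
    n_black = min(len(DEFAULT_BLACKLIST), n_rest) if n_rest >= 50 else 0
    n_mito = min(max(5, round(0.01 * n_genes)), n_rest - n_black) if n_rest - n_black > 10 else 0
    n_cc = round(0.05 * n_rest)
    n_glial = round(0.10 * n_rest)
    n_eff = round(0.30 * n_rest)
    n_hk = n_rest - n_black - n_mito - n_cc - n_glial - n_eff
    if n_hk < 0:  # tiny catalogs: fall back to housekeeping only
        n_cc = n_glial = n_eff = 0
        n_hk = n_rest - n_black - n_mito

    def const_curve(c: float) -> Callable:
        return lambda t: np.full_like(np.asarray(t, float), c)

    for i in range(n_eff):
        high = float(rng.lognormal(np.log(2.5), 0.4))
        low = 0.1 * high
        p = float(rng.uniform(0.7, 1.5))
        programs.append(GeneProgram(
            gene_id=f"Eff{i:04d}", gene_class="effector_ramp",
            mean_curve=(lambda lo, hi, pw: (lambda t: lo + hi * (np.asarray(t, float) / 100.0) ** pw))(low, high, p),
            dispersion=2.0, baseline=low,
        ))
    a, b = CLUSTER_INTERVALS["NPC"]
    for i in range(n_cc):
        high = float(rng.lognormal(np.log(3.0), 0.4))
        programs.append(GeneProgram(
            gene_id=f"Cc{i:04d}", gene_class="cellcycle",
            mean_curve=_interval_curve(a, b, 0.01 * high, high, scale=1.2),
            dispersion=2.0, baseline=0.01 * high,
        ))
    for i in range(n_glial):
        cluster = GLIAL_CLUSTERS[i % len(GLIAL_CLUSTERS)]
        high = float(rng.lognormal(np.log(3.0), 0.4))
        programs.append(GeneProgram(
            gene_id=f"Gl{cluster}{i:04d}", gene_class="glial",
            mean_curve=const_curve(0.02 * high), dispersion=2.0,
            baseline=0.02 * high, glial_cluster=cluster,
        ))
        programs[-1].glial_high = high  # type: ignore[attr-defined]
    hk_sum = 0.0
    for i in range(n_hk):
        c = float(rng.lognormal(np.log(6.0), 0.4))
        hk_sum += c
        programs.append(GeneProgram(
            gene_id=f"Hk{i:04d}", gene_class="housekeeping",
            mean_curve=const_curve(c), dispersion=2.0, baseline=c,
        ))
    # Mitochondrial genes: tight dispersion and a total budget of ~0.4% of
    # the library so clean nuclei sit safely below the 1% QC threshold.
    for i in range(n_mito):
        c = 0.005 * max(hk_sum, 10.0) / max(1, n_mito)
        programs.append(GeneProgram(
            gene_id=f"mt-G{i:02d}", gene_class="mito",
            mean_curve=const_curve(c), dispersion=100.0, baseline=c,
        ))
    for i in range(n_black):
        c = float(rng.lognormal(np.log(2.0), 0.5))
        programs.append(GeneProgram(
            gene_id=DEFAULT_BLACKLIST[i], gene_class="blacklist_like",
            mean_curve=const_curve(c), dispersion=1.0, baseline=c,
        ))

    # --- planted regulons: couple effector targets to the first TFs -------
    tf_programs = [p for p in programs if p.gene_class == "tf_switch"]
    eff_idx = [i for i, p in enumerate(programs) if p.gene_class == "effector_ramp"]
    n_reg = min(n_regulons, len(tf_programs))
    free = list(eff_idx)
    for r in range(n_reg):
        tf = tf_programs[r]
        take = min(targets_per_regulon, len(free))
        if take < 5:
            break
        chosen = rng.choice(len(free), size=take, replace=False)
        chosen_idx = sorted(free[int(c)] for c in chosen)
        free = [i for i in free if i not in set(chosen_idx)]
        for gi in chosen_idx:
            g = programs[gi]
            amp = float(rng.lognormal(np.log(2.5), 0.3))
            low = 0.03 * amp
            curve = (lambda t0, d, lo, hi: _switch_curve(t0, d, lo, hi))(
                tf.switch_time, tf.direction, low, amp)
            programs[gi] = replace(g, mean_curve=curve, baseline=low,
                                   regulon=tf.gene_id)
    return programs


def make_clustered_programs(
    n_genes: int = 2000,
    n_markers_per_cluster: int = 15,
    seed: int = 0,
) -> list[GeneProgram]:
    """Gene catalog for a *discrete* 10-cluster simulation.

    Each lineage cluster receives sharp interval-indicator marker programs
    (on at its left boundary, off at its right), so nuclei carry a
    cluster-level expression code on top of the housekeeping background.
    Used to exercise graph clustering against planted discrete labels.
    """
    rng = np.random.default_rng(seed)
    programs: list[GeneProgram] = []
    for cluster in LINEAGE_ORDER:
        a, b = CLUSTER_INTERVALS[cluster]
        for i in range(n_markers_per_cluster):
            high = float(rng.lognormal(np.log(5.0), 0.3))
            programs.append(GeneProgram(
                gene_id=f"Mk{cluster}{i:03d}", gene_class="tf_switch",
                mean_curve=_interval_curve(a, b, 0.02 * high, high, scale=0.7),
                dispersion=4.0, switch_time=float(a), direction="on_off_on",
                baseline=0.02 * high,
            ))
    n_used = len(programs)
    rest = make_gene_programs(max(n_genes - n_used, 100), n_tf=0, seed=seed + 1)
    return programs + rest


# ---------------------------------------------------------------------------
# Cohort designs
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Sampling design of one dataset of birthdated cohorts.

    ``densities`` maps each cohort age (weeks) to a mixture over pseudotime:
    a list of (weight, mean, sd) components (sd == 0 is a point mass). Each
    mixture must sum to weight 1 and cohort mean-t must be nondecreasing
    with age.
    """

    cohort_ages: list[float]
    densities: dict[float, list[tuple[float, float, float]]]
    n_nuclei: dict[float, int]
    off_trajectory_fractions: dict[str, float] = field(default_factory=dict)
    batch: str = "d1"
    lib_scale: float = 1.0
    lib_sigma: float = 0.35

    def __post_init__(self) -> None:
        if not self.cohort_ages:
            raise ValueError("design has no cohorts")
        means = []
        for age in self.cohort_ages:
            comps = self.densities[age]
            w = sum(c[0] for c in comps)
            if abs(w - 1.0) > 1e-8:
                raise ValueError(f"cohort {age}: mixture weights sum to {w}, not 1")
            means.append(sum(c[0] * c[1] for c in comps))
        if any(b < a - 1e-9 for a, b in zip(means, means[1:])):
            raise ValueError("cohort mean pseudotime must be nondecreasing with age")
        if any(f < 0 for f in self.off_trajectory_fractions.values()):
            raise ValueError("off-trajectory fractions must be nonnegative")
        if sum(self.off_trajectory_fractions.values()) >= 1.0:
            raise ValueError("off-trajectory fractions must sum to < 1")


#: Default four-mode cohort densities: modes at t = 10/30/55/85 (the four
#: cellular states), with weight shifting toward later modes as cohorts age.
_DEFAULT_MODES = (10.0, 30.0, 55.0, 85.0)
_DEFAULT_SD = 4.0
_DEFAULT_WEIGHTS = {
    1.0: (0.45, 0.30, 0.20, 0.05),
    2.0: (0.25, 0.25, 0.40, 0.10),
    3.0: (0.18, 0.17, 0.45, 0.20),
    4.0: (0.10, 0.10, 0.45, 0.35),
    5.0: (0.08, 0.07, 0.35, 0.50),
    8.0: (0.05, 0.05, 0.20, 0.70),
}

DEFAULT_OFF_TRAJECTORY = {"Astro": 0.06, "OPC": 0.02, "Oligo": 0.03, "Peri": 0.004}


def default_design(
    cohort_ages: Sequence[float] = (1, 2, 4, 8),
    n_per_cohort: int = 600,
    batch: str = "d1",
    off_trajectory: dict[str, float] | None = None,
) -> CohortDesign:
    """Dataset-1-style design (cohorts at 1/2/4/8 wk; use (2,3,4,5,8) for
    the dataset-2-style design)."""
    ages = [float(a) for a in cohort_ages]
    dens = {
        a: [(w, m, _DEFAULT_SD) for w, m in zip(_DEFAULT_WEIGHTS[a], _DEFAULT_MODES)]
        for a in ages
    }
    off = DEFAULT_OFF_TRAJECTORY if off_trajectory is None else off_trajectory
    return CohortDesign(ages, dens, {a: n_per_cohort for a in ages},
                        dict(off), batch=batch)


def clustered_design(n_nuclei: int = 3000,
                     off_trajectory: dict[str, float] | None = None) -> CohortDesign:
    """Single-cohort design concentrating nuclei at lineage-cluster centers,
    for discrete-cluster recovery experiments (pairs with
    :func:`make_clustered_programs`)."""
    comps = []
    for cluster in LINEAGE_ORDER:
        a, b = CLUSTER_INTERVALS[cluster]
        comps.append((1.0 / len(LINEAGE_ORDER), (a + b) / 2.0, (b - a) / 6.0))
    off = {"Astro": 0.08, "OPC": 0.05} if off_trajectory is None else off_trajectory
    return CohortDesign([4.0], {4.0: comps}, {4.0: n_nuclei}, off)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    counts: CountMatrix
    truth: pd.DataFrame        # one row per nucleus, aligned with columns
    gene_truth: pd.DataFrame   # one row per gene

    def regulon_truth(self) -> RegulonSet:
        """Planted regulons as a RegulonSet (TF -> target genes)."""
        rs = RegulonSet()
        gt = self.gene_truth
        for tf, grp in gt[gt["regulon"] != ""].groupby("regulon"):
            rs.regulons[str(tf)] = list(grp["gene"])
            rs.extended[str(tf)] = False
        return rs


def _sample_t(rng: np.random.Generator, comps: list[tuple[float, float, float]],
              n: int) -> np.ndarray:
    w = np.array([c[0] for c in comps])
    which = rng.choice(len(comps), size=n, p=w / w.sum())
    t = np.empty(n)
    for i, (_, m, sd) in enumerate(comps):
        mask = which == i
        k = int(mask.sum())
        if sd == 0:
            t[mask] = m
        else:
            draw = rng.normal(m, sd, size=k)
            # reflect out-of-range draws back into [0, 100]
            draw = np.abs(draw)
            draw = 100.0 - np.abs(100.0 - draw)
            t[mask] = np.clip(draw, 0.0, 100.0)
    return t


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               theta: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB draw; theta = inf gives the Poisson limit."""
    mu = np.maximum(mu, 0.0)
    out = np.zeros(mu.shape, dtype=np.int64)
    finite = np.isfinite(theta)
    if np.any(finite):
        th = theta[finite][:, None] if theta.ndim == 1 else theta[finite]
        lam = rng.gamma(np.broadcast_to(th, mu[finite].shape),
                        mu[finite] / th)
        out[finite] = rng.poisson(lam)
    if np.any(~finite):
        out[~finite] = rng.poisson(mu[~finite])
    return out


def simulate_cohorts(programs: list[GeneProgram], design: CohortDesign,
                     seed: int = 0) -> SimulatedDataset:
    """Draw a full dataset from the planted model.

    Per nucleus: pseudotime from its cohort density (or an off-trajectory
    glial identity), a log-normal library factor; per gene: NB counts around
    ``lib * mean_curve(t)``. Off-trajectory nuclei express constant programs
    plus their own cluster's glial genes; trajectory programs fall back to
    their baseline.
    """
    if not programs:
        raise ValueError("programs must be nonempty")
    rng = np.random.default_rng(seed)
    genes = [p.gene_id for p in programs]

    barcodes: list[str] = []
    cohort_col: list[float] = []
    t_col: list[float] = []
    cluster_col: list[str] = []
    batch_col: list[str] = []

    for age in design.cohort_ages:
        n = design.n_nuclei[age]
        n_off = {c: int(round(f * n))
                 for c, f in design.off_trajectory_fractions.items()}
        n_traj = n - sum(n_off.values())
        if n_traj < 0:
            raise ValueError("off-trajectory fractions exceed cohort size")
        t = np.sort(_sample_t(rng, design.densities[age], n_traj))
        for ti in t:
            t_col.append(float(ti))
            cluster_col.append("")
        for cl, k in n_off.items():
            for _ in range(k):
                t_col.append(np.nan)
                cluster_col.append(cl)
        for j in range(n):
            barcodes.append(f"{design.batch}_w{age:g}_{j:05d}")
            cohort_col.append(age)
            batch_col.append(design.batch)

    t_arr = np.array(t_col)
    on_traj = ~np.isnan(t_arr)
    clusters = np.array(cluster_col, dtype=object)
    clusters[on_traj] = true_cluster_of(t_arr[on_traj])

    n_total = len(barcodes)
    lib = design.lib_scale * rng.lognormal(0.0, design.lib_sigma, size=n_total)

    # Expected-count matrix, genes x nuclei.
    mu = np.empty((len(programs), n_total))
    t_eval = np.where(on_traj, t_arr, 0.0)
    for gi, p in enumerate(programs):
        row = np.asarray(p.mean_curve(t_eval), dtype=float)
        if p.gene_class not in _CONSTANT_CLASSES:
            row = np.where(on_traj, row, p.baseline)
        if p.gene_class == "glial" and p.glial_cluster is not None:
            high = getattr(p, "glial_high", p.baseline * 50.0)
            row = np.where(clusters == p.glial_cluster, high, row)
        mu[gi] = row * lib
    theta = np.array([p.dispersion for p in programs])
    counts = _nb_sample(rng, mu, theta)

    truth = pd.DataFrame({
        "barcode": barcodes,
        "cohort": cohort_col,
        "true_t": t_arr,
        "true_cluster": clusters,
        "true_state": true_state_of(t_arr),
        "is_doublet": False,
        "is_lowq": False,
        "lowq_mode": "",
        "batch": batch_col,
    })
    gene_truth = pd.DataFrame({
        "gene": genes,
        "class": [p.gene_class for p in programs],
        "switch_time": [p.switch_time if p.switch_time is not None else np.nan
                        for p in programs],
        "direction": [p.direction or "" for p in programs],
        "dispersion": theta,
        "regulon": [p.regulon or "" for p in programs],
    })
    cm = CountMatrix(sp.csc_matrix(counts), genes, barcodes)
    return SimulatedDataset(cm, truth, gene_truth)


def inject_artifacts(ds: SimulatedDataset, doublet_rate: float = 0.0,
                     lowq_rate: float = 0.0, mito_boost: float = 8.0,
                     seed: int = 0, lowfeat_frac: float = 0.6) -> SimulatedDataset:
    """Append doublets and degrade a subset of nuclei into low-quality ones.

    Doublets are column sums of two distinct randomly chosen nuclei, appended
    as new columns. ``round(lowq_rate * n)`` existing nuclei are degraded:
    a ``lowfeat_frac`` share has its library binomially thinned below the
    feature threshold, the rest get mitochondrial counts multiplied by
    ``mito_boost`` (pushing the Mt fraction above the QC cut). All artifacts
    are flagged in the truth table. Zero rates return the dataset unchanged.
    """
    for name, r in (("doublet_rate", doublet_rate), ("lowq_rate", lowq_rate)):
        if not (0.0 <= r <= 0.3):
            raise ValueError(f"{name} must be in [0, 0.3]")
    if doublet_rate == 0.0 and lowq_rate == 0.0:
        return ds

    rng = np.random.default_rng(seed)
    mat = ds.counts.matrix.toarray()
    n_genes, n = mat.shape
    truth = ds.truth.copy()

    n_lowq = int(round(lowq_rate * n))
    lowq_idx = rng.choice(n, size=n_lowq, replace=False) if n_lowq else np.array([], int)
    n_lf = int(round(lowfeat_frac * n_lowq))
    lf_idx, hm_idx = lowq_idx[:n_lf], lowq_idx[n_lf:]
    mito_rows = np.array([g.startswith("mt-") for g in ds.counts.genes])

    for j in lf_idx:
        mat[:, j] = rng.binomial(mat[:, j], 0.08)
    if hm_idx.size and mito_rows.any():
        block = mat[np.ix_(mito_rows, hm_idx)]
        mat[np.ix_(mito_rows, hm_idx)] = np.rint(block * mito_boost).astype(np.int64)
    truth.loc[truth.index[lowq_idx], "is_lowq"] = True
    truth.loc[truth.index[lf_idx], "lowq_mode"] = "low_features"
    truth.loc[truth.index[hm_idx], "lowq_mode"] = "high_mito"

    n_dbl = int(round(doublet_rate * n))
    new_cols, new_rows = [], []
    clean = np.setdiff1d(np.arange(n), lowq_idx)
    for d in range(n_dbl):
        i, j = rng.choice(clean, size=2, replace=False)
        new_cols.append(mat[:, i] + mat[:, j])
        row = truth.iloc[i].copy()
        row["barcode"] = f"doublet_{d:04d}"
        row["is_doublet"] = True
        row["true_t"] = np.nan
        row["true_cluster"] = "doublet"
        row["true_state"] = 0
        new_rows.append(row)
    if n_dbl:
        mat = np.column_stack([mat] + new_cols)
        truth = pd.concat([truth, pd.DataFrame(new_rows)], ignore_index=True)

    cm = CountMatrix(sp.csc_matrix(mat), list(ds.counts.genes),
                     list(truth["barcode"]))
    return SimulatedDataset(cm, truth.reset_index(drop=True), ds.gene_truth.copy())
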