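# neurotraj

Trajectory analysis of **birthdated single-nucleus RNA-seq cohorts**, built
for the study design used in adult hippocampal neurogenesis: cohorts of
cells labeled at one induction time and sampled at known ages (e.g. 1, 2, 4
and 8 weeks), profiled by snRNA-seq, and expected to lie on a single
developmental trajectory from radial glia-like stem cells (RGL) through
progenitors (NPC), neuroblasts (NB) and immature granule cells (GCimm) to
mature granule cells (GCmat), with off-trajectory glial populations.

It is a library first (importable API plus `examples/`), with a thin
`neurotraj` CLI over the cached pipeline runner for shell use.

## What it computes

Given a gene-by-nucleus count matrix (Matrix Market triplet) and per-nucleus
cohort labels, the pipeline runs:

1. **QC and normalization** — nuclei with <1000 detected features, >1%
   mitochondrial counts, robust multivariate outliers or artificial-doublet
   kNN flags are removed; features need >20 molecules and a detection
   fraction strictly inside (1%, 80%), minus a sex/stress blacklist;
   pooled (quick-cluster) size factors, log2(x/sf + 1), top-3000 HVGs.
2. **Clustering** — 20-PC PCA, mutual k-nearest-neighbor graph (k = 40,
   Pearson similarity), components of ≤30 nodes dropped, Louvain
   communities with a merge-only refinement (pairs separated by fewer than
   5 genes at FC ≥ 1.5 and FDR ≤ 0.05 are merged), pairwise Welch-t DEGs
   and aggregated marker ranks.
3. **Integration** (optional) — mutual-nearest-neighbor batch correction in
   PC space and kNN plurality label transfer with confidence.
4. **Pseudotime** — a principal curve through the lineage clusters in
   3-dim PCA space (MST initialization from the root cluster, iterated
   projection + local-linear smoothing); arc length rescaled to t ∈ [0, 100].
5. **States** — per-cohort Gaussian kernel densities over t; local maxima
   of the pooled density and the valleys between them partition the axis
   into cellular states; 5-unit windows around the peaks define the state
   nucleus groups.
6. **TF cascades** — per TF, a likelihood ratio test of a cubic-spline
   smooth vs a constant fit (2ΔlogL ~ χ², BH-corrected); significant TFs
   are binarized along the lineage by per-cluster detection fraction with
   hysteresis, and on/off switch events are ordered into a cascade.
7. **Regulons** — AUCell-style activity (area under the recovery curve of
   a regulon's targets within the top 5% of each nucleus's expression
   ranking) and the regulon specificity score
   RSS(r, s) = 1 − √JSD(P_r, G_s) (Jensen–Shannon divergence, log base 2)
   between consecutive states.

A first-class **synthetic-cohort generator** plants every quantity the
pipeline is meant to recover — pseudotime per nucleus, cluster and state
labels, TF switch times and directions, regulon memberships, doublets and
low-quality nuclei — so each stage is verifiable by parameter recovery
without any external download.

## Worked example

```sh
python examples/03_pseudotime_and_states.py
```

prints (abridged):

```
lineage nuclei: 2128; curve converged in 10 iterations; Spearman rho vs planted t: 0.973
density peaks at t = [7.2, 32.5, 51.8, 75.8]
state intervals: [(0.0, 20.2), (20.2, 40.5), (40.5, 63.8), (63.8, 100.0)]
```

2128 of 2400 simulated nuclei belong to the neuronal lineage (glia are
excluded); the inferred pseudotime orders them almost identically to the
planted ordering (ρ = 0.97); the pooled density shows four peaks separated
by valleys, and the valleys cut the axis into the four cellular states the
generator planted. The other examples cover simulation (`01`), cluster
recovery (`02`, ARI ≈ 0.99 on a 10-cluster simulation), the TF switching
cascade (`04`, switch-time ρ ≈ 0.93), regulon specificity between states
(`05`) and the cached end-to-end pipeline (`06`).

The same thing from a shell:

```sh
neurotraj run --out myrun --seed 1          # simulate → … → regulons
neurotraj run --out myrun --seed 1          # all stages reported cached
```

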