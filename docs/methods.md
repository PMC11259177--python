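# Methods

This note documents the models and procedures implemented in `neurotraj`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that affect results.

## The analysis model

The package assumes the data are nuclei drawn from a **single developmental
trajectory** — a one-dimensional manifold in expression space running from
radial glia-like stem cells (RGL) through proliferating progenitors (NPC),
postmitotic neuroblasts (NB1/NB2) and immature granule cells
(GCimm1/GCimm2) to young and mature granule cells (GCyoung/GCmat) — plus
off-trajectory glial populations (astrocytes, OPC, oligodendrocytes,
pericytes) and technical artifacts (doublets, low-quality nuclei). Cohorts
labeled at one induction time and sampled at increasing ages populate
progressively later parts of the trajectory, which is the package's main
internal consistency check: mean pseudotime per cohort must increase with
cohort age.

### QC

Per nucleus: library size, detected features, mitochondrial fraction
(genes with a configurable prefix, default `mt-`), and an
artificial-doublet score. Removal rules, with defaults matching standard
snRNA-seq practice for this tissue: fewer than 1000 detected features;
mitochondrial fraction above 1%; a robust multivariate outlier rule; a
doublet flag. The multivariate rule is per-metric robust z-scores
((x − median)/MAD) on the directional tails — *low* library size, *low*
features, *high* Mt fraction — flagged at |z| > 3. A skew-adjusted
projection estimator would serve the same intent; the per-metric rule was
chosen because it is reproducible from first principles and its reasons
are attributable per nucleus.

The doublet scorer synthesizes artificial doublets as column sums of
random nucleus pairs, co-embeds real and artificial profiles in PC space
of log library-normalized counts, and scores each nucleus by the fraction
of its k = 20 nearest neighbors that are artificial. The flag threshold is
a multiple (default 2×) of the chance-level artificial fraction
n_art/(n_art + n): within-cluster artificial doublets land inside real
clusters, so a sub-chance threshold would flag large numbers of singlets.
Scores are primarily a *ranking*; the threshold is config.

Features are kept when they carry more than 20 molecules and are detected
in more than 1% and fewer than 80% of the filtered nuclei; a 21-gene
sex/stress blacklist (`simulate.DEFAULT_BLACKLIST`) is removed and is
editable config.

### Normalization

Quick clustering (mutual-kNN k = 10 on rank-transformed profiles +
Louvain, minimum cluster size 50 with merge fallback) groups similar
nuclei per batch; size factors are median count ratios to the cluster
pseudo-bulk, rescaled across clusters via pseudo-bulk median ratios, then
globally scaled to mean 1; values are log2(x/sf + 1). **Size factors are
estimated on the full nucleus-filtered matrix and only then restricted to
the retained features.** The feature rules above remove exactly the
ubiquitous, mostly non-differential genes that median-ratio rescaling
relies on; estimating factors before the feature cut keeps the non-DE
majority assumption intact. (On synthetic data, estimating after the cut
injected a quick-cluster artifact into the PCs and halved pseudotime
recovery.)

HVGs: a lowess mean–variance trend (span 0.3) on log-expression;
biological variance = total − trend; top 3000 by biological variance, ties
by gene id; constant genes rank last by definition.

### Graph and clustering

PCA (d = 20, per-gene centered, deterministic sign convention: the
largest-|loading| entry of each component is positive). Similarity is the
Pearson correlation of PC rows; the graph keeps an edge only for mutual
k-nearest neighbors (k = 40, ties broken by nucleus index), and connected
components of ≤30 nodes are dropped. Louvain (igraph multilevel,
resolution 1.0, seeded RNG; negative edge weights clipped to 0 for
modularity — topology is unaffected). Refinement is merge-only: the pair
of (graph-adjacent) clusters with the fewest genes at FC ≥ 1.5 and
q ≤ 0.05 between them is merged while that count is below 5; always
merging the globally smallest pair (ties by name) makes the fixed point
independent of scan order, and every merge is logged.

Differential expression is a Welch t-test per gene on log-normalized
values with Benjamini–Hochberg correction across all tested genes; log2FC
uses expm1-averaged group means with a pseudo-count, the common
single-cell convention. Markers are up-regulated DEGs ranked by their
worst rank across all pairwise comparisons.

### Integration

Batch correction operates in PC space (downstream consumers — graph,
pseudotime — read PC coordinates). MNN pairs are found on centered,
cosine-normalized coordinates; pair vectors (ref − query, raw space) are
kernel-averaged with Gaussian weights anchored at each pair's **midpoint**
— chosen so that for identical batches the symmetric pairs cancel and the
correction is exactly zero — with σ defaulting to the median
query-to-anchor distance. Because one pass under-corrects large shifts
(pair selection biases toward the facing edges of the clouds), the pass is
iterated until the incremental displacement is below 1% of the first
pass's (max 8 passes). Label transfer is a kNN plurality vote (k = 20)
with the vote fraction as confidence; queries below 0.5 confidence and
labels transferred to fewer than 10 queries are left unassigned.

### Pseudotime and states

The curve is fitted in 3-dim PCA space by default (externally supplied
3-dim coordinates are accepted); initialization is the minimum-spanning
tree over cluster centroids, following the path from the root cluster
(default RGL) to its farthest leaf. Iterations alternate projecting nuclei
onto the piecewise-linear curve and re-smoothing each coordinate against
arc-length position with **degree-1 lowess** (span 0.2, ~100 control
points), stopping when the mean projection movement falls below 1e-3 of
the embedding scale (max 50 iterations, warned otherwise). A degree-0
moving average was rejected: its endpoint shrinkage makes the iteration
drift instead of converge. Pseudotime is arc length rescaled to [0, 100]
with the root at 0, so the 5-unit peak windows have a fixed meaning.
Only the single root→terminal path is kept; side branches join via their
projection onto the main curve. Within the terminal cluster, nuclei whose
mean z-scored ventral-signature expression exceeds 2 are excluded before
fitting; the ventral gene list ships empty (user config) and the synthetic
generator plants its own.

Densities are Gaussian KDEs on the fixed grid t = 0..100 step 0.25, with
Silverman bandwidth floored at 1 t-unit (this also handles point masses),
each normalized to integrate to 1. States: local maxima of the pooled
density with prominence ≥ 5% of the maximum are peaks; the argmin between
consecutive peaks is a valley; valleys are state boundaries (closed-open
intervals tiling [0, 100]); peak windows are peak ± 2.5.

### TF cascades

The association screen fits a Gaussian cubic-spline smooth (df = 4 basis
columns spanning the constant) against an intercept-only model;
2ΔlogL = n·log(RSS0/RSS1) is referred to χ²(df − 1), constant vectors get
p = 1, and BH correction runs across the TF universe (the catalog is a
user-supplied list; synthetic runs use the generator's truth). The LRT is
asymptotically calibrated for non-Gaussian errors as well; the suite
checks the type-I error on 1000 null genes lies in [0.03, 0.07].

Switch calls binarize the per-cluster detection fraction (fraction of
nuclei with a nonzero count; clusters with <5 nuclei excluded) along the
lineage order with hysteresis: expressed at ≥ 0.25, silent at ≤ 0.10,
carry the previous state in between. The profile is first rescaled to its
own [min, max] range (config `normalize_range`): absolute thresholds make
call timing depend on a gene's expression amplitude and miss weakly
expressed TFs, while the normalized rule recovers all planted switches at
switch-time Spearman ≈ 0.92 against a ~0.98 ceiling imposed by
cluster-level binning. Each state change emits an event at the boundary
cluster with t_switch = mean pseudotime of the first cluster in the new
state; at most two events (largest fraction changes) are kept, supporting
off-then-on patterns. Cascades order genes by first t_switch, ties
alphabetical.

### Regulons

Co-expression regulons (when no GMT is supplied) take, per TF, the top 50
positively Spearman-correlated genes across nuclei, dropping regulons
under 10 targets; motif-based pruning is out of scope. Activity is the
recovery-curve AUC within the top 5% of each nucleus's expression ranking
(the framework's common default), normalized by the best achievable area;
ranking ties are broken by a seeded permutation recorded in the result, so
activity is invariant to monotone transforms of expression and exactly
reproducible. RSS uses the log-base-2 Jensen–Shannon divergence so both
JSD and RSS lie in [0, 1]. Consecutive-state comparisons rank regulons by
|Δ mean activity| (then |ΔRSS|) between adjacent peak-window groups and
export row-z-scored state-mean activities for heatmaps.

## The synthetic generator

Gene programs over t ∈ [0, 100]: sigmoid TF switches (logistic scale 1.8,
so a switch completes within ~8 units — sharp enough to read as
cluster-level on/off), monotone effector ramps, a cell-cycle bump confined
to the NPC interval, constant housekeeping (log-normal means, median 6),
mitochondrial genes budgeted at ~0.4% of the library with tight
dispersion (so clean nuclei sit well below the 1% QC cut), and sex/stress
blacklist-like genes named from the shipped blacklist. Switch times are
uniform on (10, 90); 62% of switches are off by default, reflecting the
predominance of shutdown events in this developmental transition. Ten
planted regulons couple effector targets to TF curves. Counts are
negative-binomial (gamma-Poisson, per-gene dispersion θ, variance
μ + μ²/θ, Poisson at θ = ∞) with log-normal library factors (σ = 0.35).

Cohort designs: four density modes at t = 10/30/55/85 (SD 4) with weights
shifting toward later modes as cohorts age; shipped designs use cohorts at
1/2/4/8 weeks and 2/3/4/5/8 weeks, 600 nuclei per cohort — a desk-scale
size chosen so the full pipeline runs in seconds while every recovery
statistic is well-powered. Off-trajectory fractions default to 6% astro,
2% OPC, 3% oligo, 0.4% pericytes. Artifacts: doublets are exact column
sums of two random clean nuclei; low-quality nuclei are either binomially
thinned below the feature threshold or mito-boosted (×8) above the Mt cut.

A second, *discrete* layout (`make_clustered_programs` +
`clustered_design`) gives every lineage cluster sharp interval-indicator
markers and concentrates sampling at cluster centers; it exists because
cluster-recovery metrics (ARI against planted labels) are only
well-defined when the planted structure is discrete — Louvain on a pure
continuum has no ground-truth partition to match.

**What the generator does not emulate:** ambient RNA, spliced/unspliced
layers, read-level noise, batch effects in gene space (the integration
stage is exercised on PC-space constructions), cell-cycle phase structure
beyond one bump, and realistic gene-gene correlation beyond the planted
programs. Passing recovery tests therefore demonstrates the pipeline's
correctness and calibration under the stated generative model, not
robustness to every artifact of real tissue.

## Numerical and reproducibility choices

Pseudotime intervals are closed-open [a, b) so states tile [0, 100]
unambiguously. All randomness flows from one root seed, expanded per stage
(`config.stage_seed`) and recorded in per-stage manifests; igraph's RNG is
seeded per Louvain call; PCA uses a fixed-seed randomized solver above
600×600 and exact SVD below. TSVs are UTF-8 with '.' decimals and a fixed
`%.6g` float format, so identical config + seed reproduces outputs
byte-for-byte. Degenerate inputs are errors, not silent defaults: zero
peaks in a density, constant PC rows, zero-library nuclei, overlapping
peak windows, and d above the achievable PCA rank all raise with the
offending object named.

## Known limitations

Cluster-level switch calls bin t_switch at cluster resolution (ordering
fidelity is capped near Spearman 0.98 on this layout). The principal curve
is single-branch by design; a second lineage (e.g. the astrocytic branch)
must be excluded before fitting. The refinement rule is one defensible
reconstruction of a manual step and is therefore logged merge-by-merge.
Co-expression regulons without motif pruning will absorb correlated
non-targets on strongly structured data; supplying curated GMT regulons is
preferred when available.
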