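"""Principal-curve pseudotime on the default trajectory and segmentation
of the pooled density into cellular states.

Fits the curve in 3-dimensional PCA space from the RGL root, compares the
inferred ordering with the planted pseudotime, and cuts the pooled density
at its valleys.
"""

import pandas as pd
from scipy.stats import spearmanr

from neurotraj import clustering as cl
from neurotraj import qc
from neurotraj import simulate as sim
from neurotraj import trajectory as tj

programs = sim.make_gene_programs(2000, 200, seed=1)
ds = sim.simulate_cohorts(programs, sim.default_design(), seed=2)
norm = qc.normalize(ds.counts, seed=0)
truth = ds.truth.set_index("barcode")

part = cl.ClusterPartition(
    list(ds.counts.barcodes),
    truth.loc[ds.counts.barcodes, "true_cluster"].to_numpy(object))
included = tj.select_lineage(part, norm)  # drops Astro/OPC/Oligo/Peri

emb = cl.embed_pca(norm, qc.select_hvgs(norm, 1000), d=3)
pos = {b: i for i, b in enumerate(emb.ids)}
coords = emb.coords[[pos[b] for b in included]]
sub = cl.ClusterPartition(included,
                          truth.loc[included, "true_cluster"].to_numpy(object))
curve, pt = tj.fit_principal_curve(coords, sub, root_cluster="RGL")
rho = spearmanr(pt.table["t"], truth.loc[included, "true_t"]).statistic
print(f"lineage nuclei: {len(included)}; curve converged in "
      f"{curve.n_iter} iterations; Spearman rho vs planted t: {rho:.3f}")

pt.table["cohort"] = truth.loc[included, "cohort"].to_numpy()
dens = tj.cohort_density(pt)
pooled = dens[dens["cohort"] == "pooled"]["density"].to_numpy()
seg = tj.segment_states(pooled)
print(f"density peaks at t = {[round(float(p), 1) for p in seg.peaks]}")
print(f"state intervals: {[(round(a, 1), round(b, 1)) for a, b in seg.states]}")
# Four peaks separated by valleys correspond to the four cellular states
# (quiescent stem cells, progenitors, immature neurons, mature neurons).
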