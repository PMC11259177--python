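import numpy as np
import pytest

from neurotraj import clustering as cl
from neurotraj import qc
from neurotraj import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """Small default-style cohort simulation shared by unit tests."""
    programs = sim.make_gene_programs(600, 60, seed=101)
    design = sim.default_design(n_per_cohort=150)
    return sim.simulate_cohorts(programs, design, seed=102), programs


@pytest.fixture(scope="session")
def small_norm(small_sim):
    ds, _ = small_sim
    return qc.normalize(ds.counts, seed=0)


@pytest.fixture(scope="session")
def true_partition(small_sim):
    ds, _ = small_sim
    truth = ds.truth.set_index("barcode")
    labels = truth.loc[ds.counts.barcodes, "true_cluster"].to_numpy(object)
    return cl.ClusterPartition(list(ds.counts.barcodes), labels)


def blob_matrix(rng, n_per, centers, n_genes=60, scale=4.0):
    """Counts for well-separated expression blobs (one per center row)."""
    cols, labels = [], []
    for ci, center in enumerate(centers):
        mu = np.asarray(center, float) * scale
        cols.append(rng.poisson(np.tile(mu[:, None], (1, n_per))))
        labels += [ci] * n_per
    mat = np.column_stack(cols)
    if mat.shape[0] < n_genes:
        pad = rng.poisson(3.0, size=(n_genes - mat.shape[0], mat.shape[1]))
        mat = np.vstack([mat, pad])
    return mat, np.array(labels)
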