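"""End-to-end pipeline runner with per-stage caching and recorded seeds.

Stages run in order simulate -> qc -> cluster -> [integrate] -> trajectory
-> tf -> regulons. Each stage writes its outputs plus a ``manifest.json``
(config snapshot, seed, hashes of upstream manifests, package version)
into its own subdirectory of the run directory; a stage whose manifest
already matches is skipped unless forced, and a changed setting re-runs
exactly the stages downstream of it. A failing stage leaves a FAILED
marker beside its partial outputs.

For synthetic runs the clusters found by Louvain are annotated by their
majority planted label (so the trajectory stage knows which clusters form
the neuronal lineage); for real data a ``cluster_names`` TSV mapping can be
dropped into the run directory instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clustering as cl
from . import qc as qcmod
from . import regulons as rg
from . import simulate as sim
from . import tf_dynamics as tf
from . import trajectory as tj
from .config import PipelineConfig, stage_seed
from .io import (CountMatrix, read_count_matrix, read_gene_sets, read_tsv,
                 write_count_matrix, write_gene_sets, write_tsv)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "cluster", "integrate", "trajectory", "tf",
          "regulons"]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=str)


class PipelineRun:
    """State carried across stages of one pipeline execution."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path,
                 force: bool = False):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.force = force
        self._manifest_hash: dict[str, str] = {}

    # -- manifest / caching ------------------------------------------------

    def _expected_manifest(self, stage: str, upstream: list[str]) -> dict:
        return {
            "stage": stage,
            "config": self.cfg.section_dict(stage) if hasattr(self.cfg, stage) else {},
            "seed": stage_seed(self.cfg.seed, stage),
            "root_seed": self.cfg.seed,
            "upstream": {u: self._manifest_hash[u] for u in upstream},
            "version": __version__,
        }

    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def _is_cached(self, stage: str, expected: dict) -> bool:
        mpath = self.out / stage / "manifest.json"
        if self.force or not mpath.exists():
            return False
        if (self.out / stage / "FAILED").exists():
            return False
        try:
            return json.loads(mpath.read_text()) == expected
        except json.JSONDecodeError:
            return False

    def _run_stage(self, stage: str, upstream: list[str], fn) -> bool:
        expected = self._expected_manifest(stage, upstream)
        sdir = self._stage_dir(stage)
        mpath = sdir / "manifest.json"
        if self._is_cached(stage, expected):
            logger.info("stage %s: cached", stage)
            self._manifest_hash[stage] = _sha(mpath)
            return False
        if mpath.exists():
            mpath.unlink()
        failed = sdir / "FAILED"
        try:
            fn(sdir, expected["seed"])
        except Exception:
            failed.write_text("stage failed; partial outputs retained\n")
            raise
        if failed.exists():
            failed.unlink()
        mpath.write_text(_canonical(expected))
        self._manifest_hash[stage] = _sha(mpath)
        logger.info("stage %s: done", stage)
        return True

    # -- stages ------------------------------------------------------------

    def stage_simulate(self, sdir: Path, seed: int) -> None:
        c = self.cfg.simulate
        if c.clustered:
            programs = sim.make_clustered_programs(c.n_genes, seed=seed)
            design = sim.clustered_design(c.n_per_cohort * len(c.cohort_ages))
        else:
            programs = sim.make_gene_programs(c.n_genes, c.n_tf,
                                              c.frac_off_switch, seed=seed)
            design = sim.default_design(c.cohort_ages, c.n_per_cohort)
        ds = sim.simulate_cohorts(programs, design, seed=seed + 1)
        ds = sim.inject_artifacts(ds, c.doublet_rate, c.lowq_rate,
                                  c.mito_boost, seed=seed + 2)
        write_count_matrix(ds.counts, sdir / "counts")
        write_tsv(ds.truth, sdir / "truth.tsv")
        write_tsv(ds.gene_truth, sdir / "gene_truth.tsv")
        write_gene_sets(ds.regulon_truth(), sdir / "regulons_truth.gmt")

    def _load_counts(self) -> CountMatrix:
        return read_count_matrix(self.out / "simulate" / "counts")

    def stage_qc(self, sdir: Path, seed: int) -> None:
        c = self.cfg.qc
        counts = self._load_counts()
        metrics = qcmod.compute_qc_metrics(counts)
        scores = qcmod.detect_doublets(counts, k=c.doublet_k, seed=seed)
        metrics.table["doublet_score"] = scores
        flags = qcmod.doublet_flag(scores, counts.n_nuclei, counts.n_nuclei,
                                   c.doublet_threshold_mult)
        kept, removed = qcmod.filter_nuclei(
            metrics, c.min_features, c.max_mito, c.mv_z_cut,
            doublet_flags=flags, use_mv_outlier=c.use_mv_outlier)
        write_tsv(metrics.table, sdir / "qc_metrics.tsv")
        write_tsv(removed, sdir / "removed_nuclei.tsv")
        filtered = counts.subset(barcodes=kept)
        genes = qcmod.filter_features(filtered, c.blacklist,
                                      c.feature_min_total, c.feature_min_frac,
                                      c.feature_max_frac)
        # size factors are estimated on the full nucleus-filtered matrix
        # (where non-trajectory genes dominate), then the normalized matrix
        # is restricted to the retained features for all downstream stages
        norm = qcmod.normalize(filtered, quick_k=c.quick_k,
                               min_cluster=c.quick_min_cluster, seed=seed)
        norm = norm.restrict_genes(genes)
        hvgs = qcmod.select_hvgs(norm, c.n_hvgs)
        norm.hvg_set = hvgs
        write_tsv(pd.DataFrame({"barcode": norm.barcodes,
                                "size_factor": norm.size_factors}),
                  sdir / "size_factors.tsv")
        (sdir / "hvgs.txt").write_text("".join(f"{g}\n" for g in hvgs))
        (sdir / "kept_genes.txt").write_text("".join(f"{g}\n" for g in genes))
        (sdir / "kept_barcodes.txt").write_text("".join(f"{b}\n" for b in kept))
        np.save(sdir / "normalized.npy", norm.values)

    def _load_norm(self) -> qcmod.NormalizedMatrix:
        qdir = self.out / "qc"
        genes = (qdir / "kept_genes.txt").read_text().split()
        barcodes = (qdir / "kept_barcodes.txt").read_text().split()
        hvgs = (qdir / "hvgs.txt").read_text().split()
        sf = read_tsv(qdir / "size_factors.tsv")["size_factor"].to_numpy()
        values = np.load(qdir / "normalized.npy")
        return qcmod.NormalizedMatrix(values, genes, barcodes, sf, hvgs)

    def stage_cluster(self, sdir: Path, seed: int) -> None:
        c = self.cfg.cluster
        norm = self._load_norm()
        emb = cl.embed_pca(norm, norm.hvg_set, d=min(c.d, len(norm.hvg_set)))
        graph = cl.build_mknn_graph(emb, k=c.k)
        graph, discarded = cl.prune_small_components(graph, c.min_component)
        part = cl.louvain_partition(graph, c.resolution, seed=seed)
        norm_kept = norm.subset_barcodes(list(graph.ids))
        part = cl.refine_partition(part, norm_kept, c.refine_min_degs,
                                   graph=graph, fc=c.fc, alpha=c.fdr)
        part = self._annotate(part)
        write_tsv(part.to_frame(), sdir / "clusters.tsv")
        edge_df = pd.DataFrame({
            "source": [graph.ids[i] for i in graph.edges[:, 0]],
            "target": [graph.ids[j] for j in graph.edges[:, 1]],
            "weight": graph.weights,
        })
        write_tsv(edge_df, sdir / "graph_edges.tsv")
        (sdir / "discarded_nuclei.txt").write_text(
            "".join(f"{b}\n" for b in discarded))
        (sdir / "merge_log.txt").write_text(
            "".join(f"{m}\n" for m in part.merge_log))
        np.save(sdir / "embedding.npy", emb.coords)
        (sdir / "embedding_ids.txt").write_text(
            "".join(f"{b}\n" for b in emb.ids))
        markers = cl.rank_markers(norm_kept, part, c.top_markers, c.fc, c.fdr)
        write_tsv(markers, sdir / "markers.tsv")

    def _annotate(self, part: cl.ClusterPartition) -> cl.ClusterPartition:
        """Name clusters by majority planted label (synthetic runs) or a
        user-supplied cluster_names.tsv mapping; raw labels otherwise."""
        mapping_file = self.out / "cluster_names.tsv"
        truth_file = self.out / "simulate" / "truth.tsv"
        if mapping_file.exists():
            m = read_tsv(mapping_file)
            return part.rename(dict(zip(m.iloc[:, 0].astype(str),
                                        m.iloc[:, 1].astype(str))))
        if truth_file.exists():
            truth = read_tsv(truth_file).set_index("barcode")
            mapping: dict[str, str] = {}
            used: dict[str, int] = {}
            for name in part.cluster_names():
                members = part.members(name)
                maj = truth.loc[members, "true_cluster"].mode()
                base = str(maj.iloc[0]) if len(maj) else name
                k = used.get(base, 0)
                used[base] = k + 1
                mapping[name] = base if k == 0 else f"{base}.{k}"
            return part.rename(mapping)
        return part

    def _load_partition(self) -> cl.ClusterPartition:
        t = read_tsv(self.out / "cluster" / "clusters.tsv")
        return cl.ClusterPartition(list(t["barcode"].astype(str)),
                                   t["cluster"].astype(str).to_numpy(object))

    def stage_integrate(self, sdir: Path, seed: int) -> None:
        from . import integration as ig
        c = self.cfg.integrate
        sc = self.cfg.simulate
        programs = sim.make_gene_programs(sc.n_genes, sc.n_tf,
                                          sc.frac_off_switch,
                                          seed=stage_seed(self.cfg.seed, "simulate"))
        design = sim.default_design(c.query_cohort_ages, c.query_n_per_cohort,
                                    batch="d2")
        query_ds = sim.simulate_cohorts(programs, design, seed=seed)
        write_tsv(query_ds.truth, sdir / "query_truth.tsv")

        norm = self._load_norm()
        part = self._load_partition()
        qkept, _ = qcmod.filter_nuclei(
            qcmod.compute_qc_metrics(query_ds.counts),
            self.cfg.qc.min_features, self.cfg.qc.max_mito,
            use_mv_outlier=False)
        qcounts = query_ds.counts.subset(
            genes=[g for g in norm.genes], barcodes=qkept)
        qnorm = qcmod.normalize(qcounts, seed=seed)
        # project both batches into the reference PC space
        emb = cl.embed_pca(norm, norm.hvg_set,
                           d=min(self.cfg.cluster.d, len(norm.hvg_set)))
        ref_ids = [b for b in part.ids]
        pos = {b: i for i, b in enumerate(emb.ids)}
        ref_coords = emb.coords[[pos[b] for b in ref_ids]]
        Xq = qnorm.subset_genes(emb.genes).T
        qcoords = (Xq - Xq.mean(axis=0)) @ emb.loadings
        corrected, model = ig.mnn_correct(ref_coords, qcoords, k=c.k)
        lab_of = dict(zip(part.ids, part.labels))
        res = ig.transfer_labels(ref_coords, [lab_of[b] for b in ref_ids],
                                 corrected, k=c.k, min_conf=c.min_conf,
                                 min_label_n=c.min_label_n)
        res.table.insert(0, "barcode", qnorm.barcodes)
        write_tsv(res.table, sdir / "transferred_labels.tsv")
        pairs = pd.DataFrame({
            "ref": [ref_ids[i] for i in model.mnn_pairs[:, 0]],
            "query": [qnorm.barcodes[j] for j in model.mnn_pairs[:, 1]],
        })
        write_tsv(pairs, sdir / "mnn_pairs.tsv")

    @staticmethod
    def _lineage_labels(part: cl.ClusterPartition) -> list[str]:
        """Cluster labels whose base name (before any '.k' split suffix)
        belongs to the neuronal lineage; every cluster if unannotated."""
        lineage = [l for l in part.cluster_names()
                   if l.split(".")[0] in sim.LINEAGE_ORDER]
        return lineage or part.cluster_names()

    def stage_trajectory(self, sdir: Path, seed: int) -> None:
        c = self.cfg.trajectory
        norm = self._load_norm()
        part = self._load_partition()
        lineage = self._lineage_labels(part)
        included = tj.select_lineage(part, norm, lineage,
                                     c.ventral_genes or None, c.ventral_z_cut)
        emb3 = cl.embed_pca(norm, norm.hvg_set, d=c.curve_dim)
        pos = {b: i for i, b in enumerate(emb3.ids)}
        idx = [pos[b] for b in included]
        sub = cl.Embedding(emb3.coords[idx], emb3.loadings,
                           emb3.explained_variance, included, emb3.genes)
        lab_of = dict(zip(part.ids, map(str, part.labels)))
        subpart = cl.ClusterPartition(
            included, np.array([lab_of[b] for b in included], dtype=object))
        roots = [l for l in set(subpart.labels)
                 if l.split(".")[0] == c.root_cluster]
        root = sorted(roots)[0] if roots else lineage[0]
        cohorts = self._cohort_map()
        curve, pt = tj.fit_principal_curve(sub, subpart, root,
                                           c.max_iter, c.tol, c.span,
                                           cohorts=cohorts)
        write_tsv(pt.table, sdir / "pseudotime.tsv")
        dens = tj.cohort_density(pt)
        write_tsv(dens, sdir / "density.tsv")
        pooled = dens[dens["cohort"] == "pooled"]["density"].to_numpy()
        seg = tj.segment_states(pooled, min_prominence=c.min_prominence,
                                window=c.window)
        states = pd.DataFrame({
            "state": np.arange(1, seg.n_states + 1),
            "start": [s[0] for s in seg.states],
            "end": [s[1] for s in seg.states],
            "peak": seg.peaks,
            "window_start": [w[0] for w in seg.peak_windows],
            "window_end": [w[1] for w in seg.peak_windows],
        })
        write_tsv(states, sdir / "states.tsv")

    def _cohort_map(self) -> dict[str, float]:
        truth_file = self.out / "simulate" / "truth.tsv"
        if truth_file.exists():
            t = read_tsv(truth_file)
            return dict(zip(t["barcode"].astype(str), t["cohort"]))
        return {}

    def _load_pseudotime(self) -> pd.DataFrame:
        return read_tsv(self.out / "trajectory" / "pseudotime.tsv")

    def _load_states(self) -> tj.StateSegmentation:
        s = read_tsv(self.out / "trajectory" / "states.tsv")
        dens = read_tsv(self.out / "trajectory" / "density.tsv")
        pooled = dens[dens["cohort"] == "pooled"]
        peaks = s["peak"].to_numpy(float)
        valleys = np.array([s["end"].iloc[i] for i in range(len(s) - 1)])
        return tj.StateSegmentation(
            peaks=peaks, valleys=valleys,
            states=[(a, b) for a, b in zip(s["start"], s["end"])],
            peak_windows=[(a, b) for a, b in zip(s["window_start"],
                                                 s["window_end"])],
            grid=pooled["t"].to_numpy(float),
            pooled_density=pooled["density"].to_numpy(float))

    def _tf_universe(self, norm: qcmod.NormalizedMatrix) -> list[str]:
        if self.cfg.tf.tf_list:
            return Path(self.cfg.tf.tf_list).read_text().split()
        gt = read_tsv(self.out / "simulate" / "gene_truth.tsv")
        tfs = list(gt.loc[gt["class"] == "tf_switch", "gene"].astype(str))
        return [g for g in tfs if g in set(norm.genes)]

    def stage_tf(self, sdir: Path, seed: int) -> None:
        c = self.cfg.tf
        norm = self._load_norm()
        part = self._load_partition()
        pt = self._load_pseudotime()
        pt = pt[pt["included"]]
        tfs = self._tf_universe(norm)
        assoc = tf.screen_tfs(norm, tfs, pt, c.df_smooth, c.fdr)
        write_tsv(assoc, sdir / "tf_association.tsv")
        sig = list(assoc.loc[assoc["significant"], "gene"])
        # order the lineage clusters by their mean fitted pseudotime
        lab_of = dict(zip(part.ids, map(str, part.labels)))
        pt = pt.assign(cluster=[lab_of.get(b, "") for b in pt["barcode"]])
        lineage = list(pt.groupby("cluster")["t"].mean().sort_values().index)
        events = tf.detect_all_switches(norm, part, lineage, pt, sig,
                                        c.on_frac, c.off_frac)
        write_tsv(events, sdir / "switch_events.tsv")
        if len(events):
            cascade, _ = tf.build_cascade(events)
            write_tsv(cascade, sdir / "cascade_order.tsv")
        else:
            write_tsv(pd.DataFrame(columns=["gene", "direction", "t_switch"]),
                      sdir / "cascade_order.tsv")

    def stage_regulons(self, sdir: Path, seed: int) -> None:
        c = self.cfg.regulons
        norm = self._load_norm()
        pt = self._load_pseudotime()
        pt = pt[pt["included"]]
        if c.gmt:
            rs = read_gene_sets(c.gmt)
        else:
            rs = read_gene_sets(self.out / "simulate" / "regulons_truth.gmt")
        sub = norm.subset_barcodes(list(pt["barcode"].astype(str)))
        act = rg.score_activity(sub, rs, c.top_fraction, seed=seed)
        out = act.values.copy()
        out.insert(0, "regulon", out.index)
        write_tsv(out, sdir / "activity.tsv")
        seg = self._load_states()
        groups = rg.assign_peak_groups(pt, seg)
        gdf = groups.reset_index()
        gdf.columns = ["barcode", "peak_group"]
        write_tsv(gdf, sdir / "peak_groups.tsv")
        rss = rg.compute_rss(act, groups)
        rss_out = rss.copy()
        rss_out.insert(0, "regulon", rss_out.index)
        rss_out.columns = ["regulon"] + [f"state_{c_}" for c_ in rss.columns]
        write_tsv(rss_out, sdir / "rss.tsv")
        comp = rg.compare_consecutive_states(rss, act, groups)
        write_tsv(comp, sdir / "state_comparison.tsv")

    # -- driver ------------------------------------------------------------

    def run(self) -> dict[str, bool]:
        """Execute all configured stages; returns {stage: ran (False = cached)}."""
        ran = {}
        ran["simulate"] = self._run_stage("simulate", [], self.stage_simulate)
        ran["qc"] = self._run_stage("qc", ["simulate"], self.stage_qc)
        ran["cluster"] = self._run_stage("cluster", ["qc"], self.stage_cluster)
        if self.cfg.integrate.enabled:
            ran["integrate"] = self._run_stage("integrate", ["cluster"],
                                               self.stage_integrate)
        ran["trajectory"] = self._run_stage("trajectory", ["cluster"],
                                            self.stage_trajectory)
        ran["tf"] = self._run_stage("tf", ["trajectory"], self.stage_tf)
        ran["regulons"] = self._run_stage("regulons", ["trajectory"],
                                          self.stage_regulons)
        return ran


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 force: bool = False) -> dict[str, bool]:
    """Run the full pipeline into ``out_dir``; see :class:`PipelineRun`."""
    return PipelineRun(config, out_dir, force=force).run()
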