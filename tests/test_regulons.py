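import numpy as np
import pandas as pd
import pytest

from neurotraj import qc
from neurotraj import regulons as rg
from neurotraj import trajectory as tj
from neurotraj.io import RegulonSet


def brute_force_auc(ranking, regulon_positions, top_x):
    """Step-curve integration oracle: cumulative regulon hits over the top
    ranks, normalized by the best achievable area."""
    hits = [1 if g in regulon_positions else 0 for g in ranking[:top_x]]
    rec = np.cumsum(hits)
    auc = rec.sum()
    best = np.minimum(np.arange(1, top_x + 1), len(regulon_positions)).sum()
    return auc / best


def activity_of(values, genes=None, barcodes=None, regs=None, **kw):
    values = np.asarray(values, float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    barcodes = barcodes or [f"B{i}" for i in range(values.shape[1])]
    return rg.score_activity((values, genes, barcodes), regs, **kw)


class TestRegulonInference:
    def test_planted_regulon_recovered(self):
        rng = np.random.default_rng(61)
        n_cells = 300
        tf_expr = rng.normal(0, 1, n_cells)
        targets = tf_expr[None, :] + rng.normal(0, 1.0, size=(40, n_cells))
        decoys = rng.normal(0, 1, size=(1000, n_cells))
        values = np.vstack([tf_expr, targets, decoys])
        genes = ["TF"] + [f"T{i}" for i in range(40)] + \
            [f"D{i}" for i in range(1000)]
        norm = qc.NormalizedMatrix(values, genes,
                                   [f"B{i}" for i in range(n_cells)],
                                   np.ones(n_cells))
        rs = rg.infer_coexpression_regulons(norm, ["TF"], n_top_targets=50)
        got = set(rs.regulons["TF"])
        assert len(got & {f"T{i}" for i in range(40)}) >= 32  # >=80%

    def test_empty_tf_list_gives_empty_set(self, small_norm):
        rs = rg.infer_coexpression_regulons(small_norm, [])
        assert len(rs) == 0

    def test_duplicated_nuclei_leave_regulons_unchanged(self):
        rng = np.random.default_rng(62)
        values = rng.normal(0, 1, size=(60, 120))
        values[1:6] += values[0]  # five coupled targets
        genes = [f"G{i}" for i in range(60)]
        n1 = qc.NormalizedMatrix(values, genes,
                                 [f"B{i}" for i in range(120)], np.ones(120))
        n2 = qc.NormalizedMatrix(np.column_stack([values, values]), genes,
                                 [f"B{i}" for i in range(240)], np.ones(240))
        r1 = rg.infer_coexpression_regulons(n1, ["G0"], n_top_targets=10,
                                            min_size=1)
        r2 = rg.infer_coexpression_regulons(n2, ["G0"], n_top_targets=10,
                                            min_size=1)
        assert r1.regulons == r2.regulons

    def test_absent_tf_skipped(self, small_norm, caplog):
        rs = rg.infer_coexpression_regulons(small_norm, ["NotAGene"])
        assert len(rs) == 0


class TestActivityAUC:
    def test_regulon_in_top_ranks_gives_auc_one(self):
        # expression puts the 5 regulon genes at the very top of 100
        values = np.concatenate([np.arange(100, 95, -1),
                                 np.arange(90, 0, -1) * 0.1])[:, None]
        regs = RegulonSet({"r": [f"G{i}" for i in range(5)]}, {"r": False})
        act = activity_of(values, regs=regs, top_fraction=0.2)
        assert act.values.loc["r"].iloc[0] == pytest.approx(1.0)

    def test_regulon_below_cutoff_gives_auc_zero(self):
        values = np.concatenate([np.arange(95, 0, -1),
                                 np.full(5, -1.0)])[:, None]
        regs = RegulonSet({"r": [f"G{i}" for i in range(95, 100)]},
                          {"r": False})
        act = activity_of(values, regs=regs, top_fraction=0.2)
        assert act.values.loc["r"].iloc[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_50_gene_toys(self, trial):
        rng = np.random.default_rng(1000 + trial)
        g = 50
        values = rng.permutation(np.arange(g, dtype=float))[:, None]
        members = rng.choice(g, size=rng.integers(3, 12), replace=False)
        genes = [f"G{i}" for i in range(g)]
        regs = RegulonSet({"r": [genes[i] for i in members]}, {"r": False})
        top_fraction = float(rng.choice([0.1, 0.2, 0.5]))
        act = activity_of(values, genes=genes, regs=regs,
                          top_fraction=top_fraction)
        ranking = [genes[i] for i in np.argsort(-values[:, 0], kind="stable")]
        expected = brute_force_auc(ranking, set(regs.regulons["r"]),
                                   int(np.ceil(top_fraction * g)))
        assert act.values.loc["r"].iloc[0] == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(63)
        values = rng.uniform(1, 10, size=(80, 6))
        regs = RegulonSet({"r": [f"G{i}" for i in range(0, 80, 7)]},
                          {"r": False})
        a = activity_of(values, regs=regs, seed=4)
        b = activity_of(np.log(values) ** 3, regs=regs, seed=4)
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_unmeasured_regulon_reported_missing(self):
        rng = np.random.default_rng(64)
        values = rng.uniform(0, 1, size=(30, 4))
        regs = RegulonSet({"r": ["NotHere"]}, {"r": False})
        act = activity_of(values, regs=regs)
        assert act.values.loc["r"].isna().all()


def make_segmentation(peaks, window=5.0):
    peaks = np.asarray(peaks, float)
    valleys = (peaks[:-1] + peaks[1:]) / 2
    bounds = [0.0, *valleys, 100.0]
    return tj.StateSegmentation(
        peaks=peaks, valleys=valleys,
        states=[(a, b) for a, b in zip(bounds, bounds[1:])],
        peak_windows=[(p - window / 2, p + window / 2) for p in peaks])


class TestPeakGroups:
    def test_center_point_assigned(self):
        seg = make_segmentation([10, 30, 55, 85])
        pt = pd.DataFrame({"barcode": ["a"], "t": [30.0]})
        groups = rg.assign_peak_groups(pt, seg)
        assert groups.loc["a"] == 2

    def test_valley_point_unlabeled(self):
        seg = make_segmentation([10, 30, 55, 85])
        pt = pd.DataFrame({"barcode": ["a"], "t": [20.0]})
        groups = rg.assign_peak_groups(pt, seg)
        assert pd.isna(groups.loc["a"])

    def test_group_sizes_match_interval_counts(self):
        rng = np.random.default_rng(65)
        seg = make_segmentation([10, 30, 55, 85])
        t = rng.uniform(0, 100, 3000)
        pt = pd.DataFrame({"barcode": [f"B{i}" for i in range(3000)], "t": t})
        groups = rg.assign_peak_groups(pt, seg)
        for g, (a, b) in enumerate(seg.peak_windows, start=1):
            direct = ((t >= a) & (t <= b)).sum()
            assert (groups == g).sum() == direct
        assert groups.notna().sum() <= 3000

    def test_overlapping_windows_rejected(self):
        seg = make_segmentation([10, 13])
        pt = pd.DataFrame({"barcode": ["a"], "t": [10.0]})
        with pytest.raises(ValueError, match="overlap"):
            rg.assign_peak_groups(pt, seg)


class TestRSS:
    def jsd_by_hand(self, p, q):
        p, q = np.asarray(p, float), np.asarray(q, float)
        m = 0.5 * (p + q)

        def kl(a, b):
            mask = a > 0
            return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
        return 0.5 * kl(p, m) + 0.5 * kl(q, m)

    def groups_series(self, labels):
        return pd.Series(labels, index=[f"B{i}" for i in range(len(labels))])

    def activity_matrix(self, values):
        values = np.asarray(values, float)
        df = pd.DataFrame(values,
                          index=[f"r{i}" for i in range(values.shape[0])],
                          columns=[f"B{i}" for i in range(values.shape[1])])
        return rg.ActivityMatrix(values=df)

    def test_group_specific_uniform_activity_gives_rss_one(self):
        act = self.activity_matrix([[0.5, 0.5, 0.0, 0.0]])
        groups = self.groups_series([1, 1, 2, 2])
        rss = rg.compute_rss(act, groups)
        assert rss.loc["r0", 1] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_vs_indicator_matches_hand_calculation(self):
        # uniform activity over 4 nuclei vs an indicator of a group of 2
        act = self.activity_matrix([[0.25, 0.25, 0.25, 0.25]])
        groups = self.groups_series([1, 1, 2, 2])
        rss = rg.compute_rss(act, groups)
        expected = 1.0 - np.sqrt(self.jsd_by_hand([0.25] * 4,
                                                  [0.5, 0.5, 0.0, 0.0]))
        assert rss.loc["r0", 1] == pytest.approx(expected, abs=1e-10)

    def test_permuting_nuclei_leaves_rss_unchanged(self):
        rng = np.random.default_rng(66)
        values = rng.uniform(0, 1, size=(3, 40))
        labels = rng.choice([1, 2, 3], 40)
        act = self.activity_matrix(values)
        groups = self.groups_series(labels)
        rss1 = rg.compute_rss(act, groups)
        perm = rng.permutation(40)
        act2 = rg.ActivityMatrix(values=act.values.iloc[:, perm])
        rss2 = rg.compute_rss(act2, groups)
        assert np.allclose(rss1.to_numpy(), rss2.to_numpy())

    def test_rss_bounded_in_unit_interval(self):
        rng = np.random.default_rng(67)
        values = rng.uniform(0, 5, size=(10, 60))
        act = self.activity_matrix(values)
        groups = self.groups_series(rng.choice([1, 2, 3, 4], 60))
        rss = rg.compute_rss(act, groups)
        assert ((rss >= 0) & (rss <= 1)).all().all()

    def test_all_zero_activity_reported_missing(self):
        act = self.activity_matrix([[0.0, 0.0, 0.0, 0.0]])
        groups = self.groups_series([1, 1, 2, 2])
        rss = rg.compute_rss(act, groups)
        assert rss.loc["r0"].isna().all()

    def test_single_group_rejected(self):
        act = self.activity_matrix([[1.0, 1.0]])
        with pytest.raises(ValueError):
            rg.compute_rss(act, self.groups_series([1, 1]))


class TestStateComparison:
    def setup_activity(self, seed=68):
        rng = np.random.default_rng(seed)
        n_per = 30
        labels = np.repeat([1, 2, 3, 4], n_per)
        base = rng.uniform(0.05, 0.1, size=(22, 4 * n_per))
        # regulons 0-9 specific to state 3, 10-19 specific to state 4
        for r in range(10):
            base[r, labels == 3] += 0.5
        for r in range(10, 20):
            base[r, labels == 4] += 0.5
        df = pd.DataFrame(base, index=[f"r{i}" for i in range(22)],
                          columns=[f"B{i}" for i in range(4 * n_per)])
        act = rg.ActivityMatrix(values=df)
        groups = pd.Series(labels, index=df.columns)
        return act, groups

    def test_state3_regulon_ranked_down_in_3_to_4(self):
        act, groups = self.setup_activity()
        rss = rg.compute_rss(act, groups)
        comp = rg.compare_consecutive_states(rss, act, groups)
        row = comp[(comp["comparison"] == "3->4") & (comp["regulon"] == "r0")]
        assert row["direction"].iloc[0] == "down"

    def test_planted_state_specific_sets_recovered(self):
        act, groups = self.setup_activity()
        rss = rg.compute_rss(act, groups)
        comp = rg.compare_consecutive_states(rss, act, groups)
        c34 = comp[comp["comparison"] == "3->4"].set_index("regulon")
        down = {f"r{i}" for i in range(10)}
        up = {f"r{i}" for i in range(10, 20)}
        assert (c34.loc[sorted(down), "direction"] == "down").mean() >= 0.9
        assert (c34.loc[sorted(up), "direction"] == "up").mean() >= 0.9

    def test_zscore_rows_standardized(self):
        act, groups = self.setup_activity()
        rss = rg.compute_rss(act, groups)
        comp = rg.compare_consecutive_states(rss, act, groups)
        z = comp.attrs["zscore"]
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-8)
        sd = z.std(axis=1, ddof=0)
        assert np.allclose(sd[sd > 0], 1.0, atol=1e-8)

    def test_fewer_than_two_groups_rejected(self):
        act, groups = self.setup_activity()
        rss = rg.compute_rss(act, groups).iloc[:, :1]
        with pytest.raises(ValueError):
            rg.compare_consecutive_states(rss, act, groups)
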