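import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnx
from cnx.errors import ParameterError, StateError
from cnx.graph import SpatialGraph
from cnx.interactions import _anova_tukey
from conftest import make_table
from oracles import tukey_hsd_reference


def _graph(roi, n, edge_pairs):
    edges = np.array(sorted(tuple(sorted(e)) for e in edge_pairs), dtype=int)
    edges = edges.reshape(-1, 2)
    return SpatialGraph(
        roi_id=roi,
        cell_ids=np.array([f"c{i + 1}" for i in range(n)]),
        edges=edges,
        lengths=np.ones(len(edges)),
        max_dist=20.0,
    )


def _table(roi, phenos, cns, condition="control", sample="s1"):
    rows = [
        (f"c{i + 1}", roi, sample, condition, i * 3.0, 0.0, p, 0)
        for i, p in enumerate(phenos)
    ]
    return make_table(rows, ("m",)).with_column("cn", cns)


class TestCountCnInteractions:
    def test_printed_formula_five_edges_ten_cells(self):
        # 5 A-B edges among 10 cells of one CN -> 5/10*100 = 50.0
        phenos = ["A"] * 5 + ["B"] * 5
        table = _table("r1", phenos, ["CN1"] * 10)
        g = _graph("r1", 10, [(i, i + 5) for i in range(5)])
        out = cnx.count_cn_interactions(table, {"r1": g})
        row = out[(out.type_a == "A") & (out.type_b == "B")].iloc[0]
        assert row["n_edges"] == 5 and row["cn_cellcount"] == 10
        assert row["normalized"] == pytest.approx(50.0)

    def test_zero_edges_zero_normalized(self):
        table = _table("r1", ["A"] * 4 + ["B"] * 4, ["CN1"] * 8)
        out = cnx.count_cn_interactions(table, {"r1": _graph("r1", 8, [(0, 1)])})
        ab = out[(out.type_a == "A") & (out.type_b == "B")].iloc[0]
        aa = out[(out.type_a == "A") & (out.type_b == "A")].iloc[0]
        assert ab["normalized"] == 0.0
        assert aa["normalized"] == pytest.approx(1 / 8 * 100)

    def test_triangle_of_three_types(self):
        table = _table("r1", ["A", "B", "C"], ["CN1"] * 3)
        g = _graph("r1", 3, [(0, 1), (1, 2), (0, 2)])
        out = cnx.count_cn_interactions(table, {"r1": g})
        for ta, tb in [("A", "B"), ("A", "C"), ("B", "C")]:
            row = out[(out.type_a == ta) & (out.type_b == tb)].iloc[0]
            assert row["n_edges"] == 1
            assert row["normalized"] == pytest.approx(100 / 3)

    def test_bridging_edges_excluded_and_reported(self):
        table = _table("r1", ["A", "A", "B"], ["CN1", "CN2", "CN2"])
        g = _graph("r1", 3, [(0, 1), (1, 2)])
        out = cnx.count_cn_interactions(table, {"r1": g})
        assert out.attrs["n_bridging_edges"] == 1
        assert out["n_edges"].sum() == 1  # only the within-CN2 A-B edge

    def test_conservation_on_synthetic_tissue(self):
        cfg = cnx.SyntheticConfig(conditions=("control",), samples_per_condition=1,
                                  rois_per_sample=2, roi_size=(150.0, 150.0), seed=4)
        table, truth = cnx.generate_tissue(cfg)
        labeled = truth.with_true_phenotypes(table)
        labeled = labeled.with_column("cn", truth.df["domain"].to_numpy())
        graphs = cnx.build_roi_graphs(labeled)
        out = cnx.count_cn_interactions(labeled, graphs)
        total_within = sum(g.n_edges for g in graphs.values()) - out.attrs[
            "n_bridging_edges"
        ]
        assert out["n_edges"].sum() == total_within

    def test_invariant_to_cell_relabeling(self):
        phenos = ["A", "B", "A", "B"]
        table = _table("r1", phenos, ["CN1"] * 4)
        g = _graph("r1", 4, [(0, 1), (2, 3)])
        out1 = cnx.count_cn_interactions(table, {"r1": g})
        # reverse row order (ids relabeled); edges updated accordingly
        df = table.df.iloc[::-1].reset_index(drop=True)
        table2 = cnx.CellTable(df, ["m"])
        g2 = _graph("r1", 4, [(3, 2), (1, 0)])
        out2 = cnx.count_cn_interactions(table2, {"r1": g2})
        cols = ["cn", "type_a", "type_b", "n_edges", "normalized"]
        pd.testing.assert_frame_equal(
            out1[cols].reset_index(drop=True), out2[cols].reset_index(drop=True)
        )

    def test_missing_labels_raise(self):
        table = _table("r1", ["A", None, "B"], ["CN1"] * 3)
        with pytest.raises(StateError):
            cnx.count_cn_interactions(table, {"r1": _graph("r1", 3, [])})


def _interactions_frame(obs_by_cond, cn="CN1", ta="A", tb="B"):
    rows = []
    for cond, values in obs_by_cond.items():
        for i, v in enumerate(values):
            rows.append({
                "roi_id": f"{cond}_r{i}", "sample_id": f"{cond}_s{i}",
                "condition": cond, "cn": cn, "type_a": ta, "type_b": tb,
                "n_edges": 0, "cn_cellcount": 100, "normalized": float(v),
            })
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        inter = _interactions_frame({"g1": [1, 2, 3], "g2": [1, 2, 3]})
        out = cnx.compare_groups(inter)
        assert out["anova_p"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert not out["significant"].any()

    def test_degenerate_zero_variance_flagged(self):
        inter = _interactions_frame({"g1": [10, 10, 10], "g2": [20, 20, 20]})
        out = cnx.compare_groups(inter)
        assert out["anova_p"].iloc[0] == 0.0
        assert out["tukey_p"].iloc[0] == 0.0
        assert out["degenerate"].all()
        assert out["significant"].all()

    def test_anova_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = {c: rng.normal(size=6) for c in ("a", "b", "c")}
        out = cnx.compare_groups(_interactions_frame(groups))
        expected = stats.f_oneway(*groups.values()).pvalue
        assert out["anova_p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tukey_matches_independent_reference(self, seed):
        rng = np.random.default_rng(seed)
        recipe = {c: rng.normal(loc=mu, size=5)
                  for c, mu in zip("abc", (0.0, 0.5, 2.0))}
        out = cnx.compare_groups(_interactions_frame(recipe))
        ref = tukey_hsd_reference(list(recipe.values()))
        conds = sorted(recipe)
        for (i, j), p_ref in ref.items():
            row = out[(out.group_a == conds[i]) & (out.group_b == conds[j])]
            assert row["tukey_p"].iloc[0] == pytest.approx(p_ref, abs=1e-6)

    def test_unequal_n_uses_tukey_kramer(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(size=n) for n in (4, 6, 8)]
        inter = _interactions_frame({c: g for c, g in zip("abc", groups)})
        out = cnx.compare_groups(inter)
        ref = tukey_hsd_reference(groups)
        for (i, j), p_ref in ref.items():
            row = out[(out.group_a == "abc"[i]) & (out.group_b == "abc"[j])]
            assert row["tukey_p"].iloc[0] == pytest.approx(p_ref, abs=1e-6)

    def test_insufficient_data_untestable_not_dropped(self):
        inter = _interactions_frame({"g1": [1.0], "g2": [2.0]})
        out = cnx.compare_groups(inter)
        assert len(out) == 1
        assert out["untestable"].all()
        assert not out["significant"].any()

    def test_single_condition_rejected(self):
        with pytest.raises(ParameterError):
            cnx.compare_groups(_interactions_frame({"g1": [1, 2, 3]}))

    def test_sample_unit_averages_rois(self):
        rows = []
        for cond, sample, vals in [("g1", "s1", [0, 10]), ("g1", "s2", [20, 30]),
                                   ("g2", "s3", [5, 5]), ("g2", "s4", [7, 9])]:
            for i, v in enumerate(vals):
                rows.append({
                    "roi_id": f"{sample}_r{i}", "sample_id": sample,
                    "condition": cond, "cn": "CN1", "type_a": "A", "type_b": "B",
                    "n_edges": 0, "cn_cellcount": 10, "normalized": float(v),
                })
        out = cnx.compare_groups(pd.DataFrame(rows), unit="sample")
        # per-sample means: g1 {5, 25}, g2 {5, 8}
        expected = stats.f_oneway([5.0, 25.0], [5.0, 8.0]).pvalue
        assert out["anova_p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(5)
        frames = [
            _interactions_frame({c: rng.normal(size=4) for c in "ab"},
                                cn="CN1", ta="A", tb=t)
            for t in "BCDE"
        ]
        inter = pd.concat(frames, ignore_index=True)
        raw = cnx.compare_groups(inter)
        adj = cnx.compare_groups(inter, p_adjust="bh")
        assert (adj["anova_p"].to_numpy() >= raw["anova_p"].to_numpy() - 1e-12).all()

    def test_dual_rule_conjunction(self):
        rng = np.random.default_rng(11)
        inter = _interactions_frame(
            {c: rng.normal(loc=mu, size=8) for c, mu in zip("abc", (0, 0.1, 3.0))}
        )
        out = cnx.compare_groups(inter, alpha=0.05)
        testable = out[~out.untestable]
        expected = (testable["anova_p"] < 0.05) & (testable["tukey_p"] < 0.05)
        assert (testable["significant"] == expected).all()


class TestAnovaTukeyHelper:
    def test_handwritten_studentized_range_oracle(self):
        # equal-n case: q = |mean_i - mean_j| / sqrt(MSE / n)
        rng = np.random.default_rng(21)
        groups = [rng.normal(loc=m, size=5) for m in (0.0, 1.0, 1.5)]
        anova_p, tukey_p, degenerate = _anova_tukey(groups)
        assert not degenerate
        k, n = 3, 5
        means = [g.mean() for g in groups]
        mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / (k * n - k)
        for (i, j), p in tukey_p.items():
            q = abs(means[i] - means[j]) / np.sqrt(mse / n)
            assert p == pytest.approx(
                float(stats.studentized_range.sf(q, k, k * n - k)), abs=1e-12
            )


class TestFilterSignificant:
    @staticmethod
    def _comparisons():
        return pd.DataFrame([
            {"cn": "CN3", "type_a": "A", "type_b": "B", "group_a": "control",
             "group_b": "35dpi", "anova_p": 0.01, "tukey_p": 0.02,
             "significant": True, "untestable": False, "degenerate": False},
            {"cn": "CN3", "type_a": "A", "type_b": "B", "group_a": "5dpi",
             "group_b": "35dpi", "anova_p": 0.01, "tukey_p": 0.01,
             "significant": True, "untestable": False, "degenerate": False},
            {"cn": "CN1", "type_a": "C", "type_b": "C", "group_a": "control",
             "group_b": "5dpi", "anova_p": 0.50, "tukey_p": 0.70,
             "significant": False, "untestable": False, "degenerate": False},
        ])

    def test_keeps_only_reference_significant(self):
        out = cnx.filter_significant(self._comparisons(), "control")
        assert len(out) == 1
        assert out.iloc[0]["cn"] == "CN3"

    def test_empty_when_nothing_significant(self):
        comp = self._comparisons()
        comp["significant"] = False
        assert len(cnx.filter_significant(comp, "control")) == 0

    def test_immune_type_restriction(self):
        out = cnx.filter_significant(self._comparisons(), "control",
                                     immune_types=["Z"])
        assert len(out) == 0

    def test_output_rows_respect_conjunction(self):
        out = cnx.filter_significant(self._comparisons(), "control")
        assert ((out["anova_p"] < 0.05) & (out["tukey_p"] < 0.05)).all()

    def test_unknown_reference_rejected(self):
        with pytest.raises(ParameterError):
            cnx.filter_significant(self._comparisons(), "mars")
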