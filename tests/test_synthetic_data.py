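import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import cnx
from cnx.errors import ConfigError, IntegrityError


def _small_cfg(**kw):
    defaults = dict(conditions=("control",), samples_per_condition=1,
                    rois_per_sample=1, roi_size=(150.0, 150.0), seed=0)
    defaults.update(kw)
    return cnx.SyntheticConfig(**defaults)


class TestGenerateTissue:
    def test_same_seed_byte_identical(self):
        cfg = _small_cfg(seed=11)
        t1, tr1 = cnx.generate_tissue(cfg)
        t2, tr2 = cnx.generate_tissue(_small_cfg(seed=11))
        assert t1.df.to_csv() == t2.df.to_csv()
        assert tr1.df.to_csv() == tr2.df.to_csv()

    def test_different_seed_differs(self):
        t1, _ = cnx.generate_tissue(_small_cfg(seed=1))
        t2, _ = cnx.generate_tissue(_small_cfg(seed=2))
        assert t1.df.to_csv() != t2.df.to_csv()

    def test_pure_domain_is_single_phenotype(self):
        cfg = _small_cfg(domains=[cnx.Domain("only", {"A": 1.0})],
                         marker_model={"A": {"m1": 1.0, "m2": 0.0}})
        table, truth = cnx.generate_tissue(cfg)
        assert (truth.df["phenotype"] == "A").all()

    def test_design_structure(self):
        cfg = cnx.SyntheticConfig(conditions=("control", "late"),
                                  samples_per_condition=2, rois_per_sample=3,
                                  roi_size=(120.0, 120.0), seed=3)
        table, _ = cnx.generate_tissue(cfg)
        assert table.df["condition"].nunique() == 2
        assert table.df["sample_id"].nunique() == 4
        assert table.df["roi_id"].nunique() == 12
        assert set(table.group_design.values()) == {"control", "late"}

    def test_composition_converges(self):
        # >= 2000 cells/domain: empirical fractions within L1 0.05 of target
        cfg = _small_cfg(roi_size=(1300.0, 1300.0), seed=5)
        table, truth = cnx.generate_tissue(cfg)
        phenos = cfg.phenotypes
        for d in cfg.domains:
            sel = truth.df["domain"] == d.name
            assert sel.sum() >= 2000
            emp = truth.df.loc[sel, "phenotype"].value_counts(normalize=True)
            l1 = sum(abs(emp.get(p, 0.0) - d.composition.get(p, 0.0))
                     for p in phenos)
            assert l1 <= 0.05

    def test_blob_layout_contiguity(self):
        cfg = _small_cfg(spatial_layout="blobs", seed=6)
        table, truth = cnx.generate_tissue(cfg)
        assert truth.df["domain"].nunique() == 3

    def test_attraction_monotone_in_theta(self):
        doms = [cnx.Domain("mucosa",
                           {"epithelial": 0.84, "CD8T": 0.08, "macrophage": 0.08})]
        means = []
        for theta in (0.0, 0.2, 0.5, 0.8):
            vals = []
            for seed in range(12):
                cfg = cnx.SyntheticConfig(
                    conditions=("late",), samples_per_condition=1,
                    rois_per_sample=3, roi_size=(200.0, 150.0),
                    cell_density=0.004, domains=doms,
                    attraction=[cnx.Attraction("late", "CD8T", "macrophage", theta)],
                    seed=seed,
                )
                table, truth = cnx.generate_tissue(cfg)
                labeled = truth.with_true_phenotypes(table)
                labeled = labeled.with_column("cn", truth.df["domain"].to_numpy())
                graphs = cnx.build_roi_graphs(labeled)
                inter = cnx.count_cn_interactions(labeled, graphs)
                sub = inter[(inter.type_a == "CD8T") & (inter.type_b == "macrophage")]
                vals.extend(sub["normalized"])
            means.append(np.mean(vals))
        assert all(means[i] < means[i + 1] for i in range(3))

    def test_theta_zero_relocates_nobody(self):
        doms = [cnx.Domain("d", {"A": 0.5, "B": 0.5})]
        mm = {"A": {"m": 1.0}, "B": {"m": 0.0}}
        base = _small_cfg(domains=doms, marker_model=mm)
        with_null = _small_cfg(
            domains=doms, marker_model=mm,
            attraction=[cnx.Attraction("control", "A", "B", 0.0)],
        )
        t1, _ = cnx.generate_tissue(base)
        t2, _ = cnx.generate_tissue(with_null)
        assert np.allclose(t1.df[["x", "y"]], t2.df[["x", "y"]])


class TestConfigValidation:
    def test_bad_composition_rejected(self):
        with pytest.raises(ConfigError, match="composition"):
            _small_cfg(domains=[cnx.Domain("d", {"A": 0.7, "B": 0.7})])

    def test_bad_theta_rejected(self):
        with pytest.raises(ConfigError):
            _small_cfg(attraction=[cnx.Attraction("control", "A", "B", 1.5)])

    def test_unknown_attraction_condition_rejected(self):
        with pytest.raises(ConfigError):
            _small_cfg(attraction=[cnx.Attraction("mars", "A", "B", 0.5)])

    def test_too_sparse_rejected(self):
        with pytest.raises(ConfigError, match=">= 10"):
            _small_cfg(roi_size=(10.0, 10.0), cell_density=0.001)


class TestTruthReport:
    def test_perfect_recovery(self):
        table, truth = cnx.generate_tissue(_small_cfg(seed=7))
        labeled = truth.with_true_phenotypes(table)
        labeled = labeled.with_column("cn", truth.df["domain"].to_numpy())
        rep = cnx.truth_report(truth, labeled)
        assert rep["ari_phenotype"] == 1.0
        assert rep["ari_domain"] == 1.0

    def test_random_labels_near_zero_ari(self):
        table, truth = cnx.generate_tissue(_small_cfg(seed=8))
        aris = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            random_cn = rng.choice(["CN1", "CN2"], size=table.n_cells)
            labeled = truth.with_true_phenotypes(table).with_column("cn", random_cn)
            aris.append(cnx.truth_report(truth, labeled)["ari_domain"])
        assert abs(np.mean(aris)) < 0.05

    def test_single_domain_ari_not_applicable(self):
        cfg = _small_cfg(domains=[cnx.Domain("only", {"A": 1.0})],
                         marker_model={"A": {"m1": 1.0}})
        table, truth = cnx.generate_tissue(cfg)
        labeled = truth.with_true_phenotypes(table).with_column(
            "cn", ["CN1"] * table.n_cells
        )
        assert cnx.truth_report(truth, labeled)["ari_domain"] is None

    def test_misaligned_tables_rejected(self):
        table, truth = cnx.generate_tissue(_small_cfg(seed=9))
        clipped = cnx.CellTable(table.df.iloc[:-1].copy(), table.marker_names)
        with pytest.raises(IntegrityError):
            truth.with_true_phenotypes(clipped)

    def test_attraction_confusion_table(self):
        table, truth = cnx.generate_tissue(_small_cfg(seed=10))
        truth.attraction = [cnx.Attraction("control", "CD8T", "macrophage", 0.5)]
        labeled = truth.with_true_phenotypes(table)
        labeled = labeled.with_column("cn", truth.df["domain"].to_numpy())
        comp = pd.DataFrame([
            {"cn": "CN1", "type_a": "CD8T", "type_b": "macrophage",
             "group_a": "control", "group_b": "late", "anova_p": 0.001,
             "tukey_p": 0.002, "significant": True, "untestable": False,
             "degenerate": False},
        ])
        rep = cnx.truth_report(truth, labeled, comparisons=comp, reference="control")
        conf = rep["attraction_confusion"]
        row = conf[(conf.type_a == "CD8T") & (conf.type_b == "macrophage")]
        assert bool(row["planted"].iloc[0]) and bool(row["detected"].iloc[0])
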