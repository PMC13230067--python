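"""Test condition differences in per-CN interactions (ANOVA + Tukey HSD).

Plants a CD8 T cell-macrophage attraction in the 'late' condition,
computes the normalized statistic (interactions per 100 CN cells per
ROI), and applies the dual decision rule: one-way ANOVA p < 0.05 AND
Tukey HSD p < 0.05 for a condition pair.
"""

import cnx

domains = [
    cnx.Domain("mucosa", {"epithelial": 0.84, "CD8T": 0.08, "macrophage": 0.08}),
    cnx.Domain("muscularis", {"SMC": 0.80, "VEC": 0.20}),
]
config = cnx.SyntheticConfig(
    conditions=("control", "early", "late"), samples_per_condition=3,
    rois_per_sample=3, roi_size=(300.0, 200.0), cell_density=0.004,
    domains=domains,
    attraction=[cnx.Attraction("late", "CD8T", "macrophage", 0.8)],
    seed=4,
)
table, truth = cnx.generate_tissue(config)
labeled = truth.with_true_phenotypes(table)

graphs = cnx.build_roi_graphs(labeled, max_dist=20.0)
comp = cnx.composition_vectors(labeled, graphs)
model = cnx.detect_neighborhoods(comp, n_cn=2, seed=0)
with_cn = cnx.assign_neighborhoods(labeled, model)

inter = cnx.count_cn_interactions(with_cn, graphs)
pair = inter[(inter.type_a == "CD8T") & (inter.type_b == "macrophage")]
print("mean normalized CD8T-macrophage statistic per CN and condition:")
print(pair.groupby(["cn", "condition"], observed=True)["normalized"]
      .mean().round(2).to_string())

comparisons = cnx.compare_groups(inter, unit="roi", alpha=0.05)
significant = cnx.filter_significant(comparisons, reference="control")
cols = ["cn", "type_a", "type_b", "group_a", "group_b", "anova_p", "tukey_p"]
print("\nsignificant vs control (ANOVA p < 0.05 AND Tukey p < 0.05):")
print(significant[cols].round(4).to_string(index=False))
# The planted pair should appear here, in the CN that maps to the
# mucosa compartment, with the 'late' condition clearly elevated; over
# many seeds the expected elevation is about threefold.
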