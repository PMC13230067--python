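"""Validation benchmarks against planted ground truth and reference oracles.

Every routine here recomputes a quality measure of the pipeline from
scratch on synthetic data: agreement of the spatial graph with a
brute-force empty-circumcircle reference, recovery of planted phenotypes
and neighborhood domains, calibration and power of the ANOVA + Tukey
decision rule, agreement of the Tukey p-values with scipy's independent
implementation, and byte-level determinism of a full pipeline rerun.

Problem sizes default to desk scale (a few hundred to a few thousand
cells per simulated dataset) so the whole battery runs in minutes on one
CPU; see the methods note for what these sizes do and do not probe.
"""

from __future__ import annotations

import hashlib
import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .graph import build_delaunay_graph, build_roi_graphs
from .interactions import _anova_tukey, compare_groups, count_cn_interactions, filter_significant
from .neighborhoods import assign_neighborhoods, composition_vectors, detect_neighborhoods
from .phenotype import cluster_phenotypes, normalize_markers
from .pipeline import RunConfig, run_pipeline
from .simulate import Attraction, Domain, SyntheticConfig, generate_tissue


# ---------------------------------------------------------------------------
# Delaunay reference
# ---------------------------------------------------------------------------

def delaunay_reference_edges(points: np.ndarray, max_dist: float) -> set:
    """Pruned Delaunay edge set by definition: O(n^4) empty-circumcircle test.

    A triangle is Delaunay iff no other point lies strictly inside its
    circumcircle; the edge set is the union of such triangles' edges,
    filtered by length. Assumes general position.
    """
    P = np.asarray(points, dtype=float)
    n = len(P)
    tri = np.array(list(combinations(range(n), 3)))
    A, B, C = P[tri[:, 0]], P[tri[:, 1]], P[tri[:, 2]]
    d = 2.0 * (
        A[:, 0] * (B[:, 1] - C[:, 1])
        + B[:, 0] * (C[:, 1] - A[:, 1])
        + C[:, 0] * (A[:, 1] - B[:, 1])
    )
    ok = np.abs(d) > 1e-12
    tri, A, B, C, d = tri[ok], A[ok], B[ok], C[ok], d[ok]
    a2, b2, c2 = (A**2).sum(1), (B**2).sum(1), (C**2).sum(1)
    ux = (a2 * (B[:, 1] - C[:, 1]) + b2 * (C[:, 1] - A[:, 1])
          + c2 * (A[:, 1] - B[:, 1])) / d
    uy = (a2 * (C[:, 0] - B[:, 0]) + b2 * (A[:, 0] - C[:, 0])
          + c2 * (B[:, 0] - A[:, 0])) / d
    centers = np.c_[ux, uy]
    r2 = ((A - centers) ** 2).sum(1)
    dist2 = ((P[None, :, :] - centers[:, None, :]) ** 2).sum(2)
    empty = ~(dist2 < r2[:, None] * (1.0 - 1e-9)).any(axis=1)
    edges = set()
    for i, j, k in tri[empty]:
        for e in ((i, j), (i, k), (j, k)):
            e = (min(e), max(e))
            if np.linalg.norm(P[e[0]] - P[e[1]]) <= max_dist:
                edges.add(e)
    return edges


def delaunay_oracle_check(n_sets: int = 100, max_n: int = 50, seed: int = 0) -> dict:
    """Fraction of random point sets whose pruned graph matches the reference."""
    matches = 0
    for i in range(n_sets):
        rng = np.random.default_rng(seed + i)
        pts = rng.uniform(0, 100, size=(int(rng.integers(5, max_n + 1)), 2))
        g = build_delaunay_graph(pts, max_dist=30.0)
        got = {tuple(e) for e in g.edges}
        if got == delaunay_reference_edges(pts, 30.0):
            matches += 1
    return {"agreement": matches / n_sets, "n": n_sets}


# ---------------------------------------------------------------------------
# Recovery benchmarks
# ---------------------------------------------------------------------------

def phenotype_recovery(n_seeds: int = 20, k_nn: int = 50, seed: int = 0) -> np.ndarray:
    """ARI of phenotype clustering vs planted truth on default marker mixtures.

    Tissues of ~350-400 cells (two 150x150 um ROIs at default density),
    clustered at the field-standard k = 50.
    """
    aris = np.empty(n_seeds)
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            conditions=("control",), samples_per_condition=1, rois_per_sample=2,
            roi_size=(150.0, 150.0), seed=seed + i,
        )
        table, truth = generate_tissue(cfg)
        model = cluster_phenotypes(normalize_markers(table), k_nn=k_nn, seed=seed + i)
        aris[i] = adjusted_rand_score(truth.df["phenotype"], model.labels)
    return aris


def cn_recovery(n_seeds: int = 20, seed: int = 0) -> np.ndarray:
    """ARI of CN detection vs the three planted domains.

    Domains are 250 um-wide strips (ROI 750x300 um) with the default
    crisp compositions; phenotypes are taken from the planted truth so
    the benchmark isolates the neighborhood stage.
    """
    aris = np.empty(n_seeds)
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            conditions=("control",), samples_per_condition=1, rois_per_sample=2,
            roi_size=(750.0, 300.0), seed=seed + i,
        )
        table, truth = generate_tissue(cfg)
        labeled = truth.with_true_phenotypes(table)
        graphs = build_roi_graphs(labeled)
        comp = composition_vectors(labeled, graphs)
        model = detect_neighborhoods(comp, n_cn=3, seed=seed + i)
        aris[i] = adjusted_rand_score(truth.df["domain"], model.labels)
    return aris


# ---------------------------------------------------------------------------
# Decision-rule calibration and power
# ---------------------------------------------------------------------------

_NULL_DOMAINS = [
    Domain("mucosa", {"epithelial": 0.84, "CD8T": 0.08, "macrophage": 0.08}),
    Domain("immune", {"CD8T": 0.50, "macrophage": 0.35, "epithelial": 0.15}),
]

_POWER_DOMAINS = [
    Domain("mucosa", {"epithelial": 0.84, "CD8T": 0.08, "macrophage": 0.08}),
    Domain("muscularis", {"SMC": 0.80, "VEC": 0.20}),
]


def _analyze(table, truth, n_cn, seed):
    labeled = truth.with_true_phenotypes(table)
    graphs = build_roi_graphs(labeled)
    comp = composition_vectors(labeled, graphs)
    model = detect_neighborhoods(comp, n_cn=n_cn, seed=seed)
    with_cn = assign_neighborhoods(labeled, model)
    inter = count_cn_interactions(with_cn, graphs)
    return with_cn, inter


def null_calibration(n_sims: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Empirical false-positive rate of the dual rule on null tissues.

    No attraction is planted, so every (CN, pair) hypothesis is null;
    3 conditions with 3 ROIs each per dataset. Returns the fraction of
    hypotheses flagged for any condition pair, and a Kolmogorov-Smirnov
    uniformity p-value for the ANOVA p-values of one well-populated
    reference hypothesis tracked across simulations.
    """
    flagged = 0
    n_hyp = 0
    ref_pvals = []
    for i in range(n_sims):
        cfg = SyntheticConfig(
            conditions=("control", "early", "late"), samples_per_condition=1,
            rois_per_sample=3, roi_size=(250.0, 150.0), cell_density=0.008,
            domains=[Domain(d.name, dict(d.composition)) for d in _NULL_DOMAINS],
            seed=seed + i,
        )
        table, truth = generate_tissue(cfg)
        _, inter = _analyze(table, truth, n_cn=2, seed=seed + i)
        comp = compare_groups(inter, alpha=alpha)
        testable = comp[~comp["untestable"]]
        per_hyp = testable.groupby(["cn", "type_a", "type_b"], observed=True)
        flagged += int(per_hyp["significant"].any().sum())
        n_hyp += per_hyp.ngroups
        ref = testable[
            (testable["cn"] == "CN1")
            & (testable["type_a"] == "epithelial")
            & (testable["type_b"] == "epithelial")
        ]
        if len(ref):
            ref_pvals.append(float(ref["anova_p"].iloc[0]))
    ks_p = float(stats.kstest(ref_pvals, "uniform").pvalue)
    return {
        "flag_rate": flagged / n_hyp,
        "ks_p": ks_p,
        "n_hypotheses": n_hyp,
        "n_sims": n_sims,
    }


def attraction_power(n_reps: int = 100, seed: int = 0, theta: float = 0.8) -> dict:
    """Detection frequency of a planted CD8T-macrophage attraction.

    The attraction is planted in the 'late' condition inside the mucosa
    domain at a strength calibrated to raise the expected normalized
    statistic about threefold over control. A replicate counts as
    detected when the pair is flagged significant vs control in the
    detected CN that overlaps the mucosa domain.
    """
    hits = 0
    ctrl_means, late_means = [], []
    for i in range(n_reps):
        cfg = SyntheticConfig(
            conditions=("control", "early", "late"), samples_per_condition=3,
            rois_per_sample=3, roi_size=(300.0, 200.0), cell_density=0.004,
            domains=[Domain(d.name, dict(d.composition)) for d in _POWER_DOMAINS],
            attraction=[Attraction("late", "CD8T", "macrophage", theta)],
            seed=seed + i,
        )
        table, truth = generate_tissue(cfg)
        with_cn, inter = _analyze(table, truth, n_cn=2, seed=seed + i)
        overlap = pd.crosstab(with_cn.df["cn"], truth.df["domain"].to_numpy())
        cn_mucosa = overlap["mucosa"].idxmax()
        comp = compare_groups(inter)
        sig = filter_significant(comp, reference="control")
        hit = (
            (sig["cn"] == cn_mucosa)
            & (sig["type_a"] == "CD8T")
            & (sig["type_b"] == "macrophage")
            & ((sig["group_a"] == "late") | (sig["group_b"] == "late"))
        ).any()
        hits += bool(hit)
        sub = inter[
            (inter["cn"] == cn_mucosa)
            & (inter["type_a"] == "CD8T")
            & (inter["type_b"] == "macrophage")
        ]
        ctrl_means.append(sub.loc[sub["condition"] == "control", "normalized"].mean())
        late_means.append(sub.loc[sub["condition"] == "late", "normalized"].mean())
    return {
        "power": hits / n_reps,
        "effect_ratio": float(np.mean(late_means) / np.mean(ctrl_means)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Tukey cross-check and pipeline determinism
# ---------------------------------------------------------------------------

def tukey_agreement(n_recipes: int = 20, seed: int = 0) -> dict:
    """Max |p - p_scipy| between our Tukey HSD p-values and scipy's.

    Seeded 3-group recipes with 5 observations per group; scipy's
    ``tukey_hsd`` is an independent implementation of the same
    studentized-range test.
    """
    worst = 0.0
    for i in range(n_recipes):
        rng = np.random.default_rng(seed + i)
        groups = [rng.normal(loc=mu, size=5) for mu in (0.0, 0.5, 2.0)]
        _, tukey_p, _ = _anova_tukey(groups)
        ref = stats.tukey_hsd(*groups)
        for (a, b), p in tukey_p.items():
            worst = max(worst, abs(p - float(ref.pvalue[a, b])))
    return {"max_abs_diff": worst, "n_recipes": n_recipes}


def pipeline_determinism(seed: int = 0, base_dir=None) -> dict:
    """Run the full pipeline twice on one config; compare output checksums."""
    sim = SyntheticConfig(
        conditions=("control", "late"), samples_per_condition=2,
        rois_per_sample=2, roi_size=(150.0, 150.0), seed=seed,
    )

    def _run(out_dir):
        cfg = RunConfig(simulate=sim, k_nn=30, n_cn=3, seed=seed,
                        reference="control", out_dir=str(out_dir))
        run_pipeline(cfg)
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(out_dir).iterdir())
        }

    with tempfile.TemporaryDirectory(dir=base_dir) as tmp:
        a = _run(Path(tmp) / "a")
        b = _run(Path(tmp) / "b")
    return {"identical": a == b, "n_artifacts": len(a)}
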