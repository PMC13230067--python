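"""Per-CN interaction counts, the normalized statistic, and group comparison.

An "interaction" is a pruned-Delaunay edge. For each ROI and CN, edges
whose two endpoints both lie in that CN are counted once per unordered
phenotype pair (A-A self-pairs count once per edge); edges bridging two
CNs are excluded from the counts and reported separately as a
diagnostic. The statistic per (ROI, CN, pair) is

    normalized = n_edges / n_cells_in_CN_in_ROI * 100

i.e. interactions per 100 CN cells, which makes ROIs of different size
and CN occupancy comparable.

Group comparison follows the fixed decision rule: one observation per
ROI (or per sample, as sensitivity analysis), one-way fixed-effects
ANOVA across conditions, Tukey HSD post-hoc p-values from the
studentized-range distribution, and a pair of conditions is called
significant for a (CN, pair) hypothesis iff ANOVA p < alpha AND its
Tukey p < alpha. No multiple-testing correction is applied across
(CN, pair) hypotheses by default; Benjamini-Hochberg on the ANOVA
p-values is available behind ``p_adjust="bh"``.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, StateError
from .graph import SpatialGraph
from .io import CellTable

ALPHA_DEFAULT = 0.05


def count_cn_interactions(
    table: CellTable, graphs: dict[str, SpatialGraph]
) -> pd.DataFrame:
    """Count within-CN phenotype-pair edges per ROI and normalize.

    Returns a long table with one row per (roi, cn, unordered phenotype
    pair) for every (roi, cn) stratum that contains at least one cell —
    including zero-count pairs, so downstream group comparisons see 0
    rather than a missing observation. Columns: roi_id, sample_id,
    condition, cn, type_a, type_b (type_a <= type_b), n_edges,
    cn_cellcount, normalized. The number of edges dropped because their
    endpoints lie in different CNs is stored in
    ``result.attrs["n_bridging_edges"]``.
    """
    df = table.df
    if df["phenotype"].isna().any():
        raise StateError("phenotype labels not assigned")
    if df["cn"].isna().any():
        raise StateError("CN labels not assigned")
    missing = set(df["roi_id"]) - set(graphs)
    if missing:
        raise StateError(f"no spatial graph for ROIs {sorted(missing)[:5]}")

    phenotypes = sorted(pd.unique(df["phenotype"]))
    pairs = list(itertools.combinations_with_replacement(phenotypes, 2))
    pheno = df["phenotype"].to_numpy()
    cn = df["cn"].to_numpy()
    roi_meta = df[["roi_id", "sample_id", "condition"]].drop_duplicates("roi_id")
    roi_meta = roi_meta.set_index("roi_id")

    rows = []
    n_bridging = 0
    for roi, sub in df.groupby("roi_id", observed=True, sort=True):
        pos = sub.index.to_numpy()
        g = graphs[roi]
        cellcounts = sub.groupby("cn", observed=True).size()
        edge_counts: dict[tuple, int] = {}
        if len(g.edges):
            a, b = pos[g.edges[:, 0]], pos[g.edges[:, 1]]
            same = cn[a] == cn[b]
            n_bridging += int((~same).sum())
            for ai, bi in zip(a[same], b[same]):
                ta, tb = sorted((pheno[ai], pheno[bi]))
                key = (cn[ai], ta, tb)
                edge_counts[key] = edge_counts.get(key, 0) + 1
        meta = roi_meta.loc[roi]
        for cn_label, count in cellcounts.items():
            for ta, tb in pairs:
                n_e = edge_counts.get((cn_label, ta, tb), 0)
                rows.append(
                    (roi, meta["sample_id"], meta["condition"], cn_label,
                     ta, tb, n_e, int(count), n_e / count * 100.0)
                )
    out = pd.DataFrame(
        rows,
        columns=["roi_id", "sample_id", "condition", "cn", "type_a", "type_b",
                 "n_edges", "cn_cellcount", "normalized"],
    )
    out.attrs["n_bridging_edges"] = n_bridging
    return out


def _anova_tukey(groups: list[np.ndarray]):
    """One-way ANOVA p and Tukey HSD p per group pair; flags degeneracy.

    The F statistic is the usual between/within mean-square ratio; Tukey
    p-values use the Tukey-Kramer q statistic

        q_ij = |mean_i - mean_j| / sqrt(MSE / 2 * (1/n_i + 1/n_j))

    against the studentized-range distribution with k groups and N - k
    error degrees of freedom (equal-n HSD is the special case).

    Zero within-group variance is handled explicitly: identical group
    means give p = 1, different means give p = 0 (infinite F / q), with
    a degenerate-variance flag either way.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    pair_idx = list(itertools.combinations(range(k), 2))
    if ssw <= 0:
        equal = [means[i] == means[j] for i, j in pair_idx]
        anova_p = 1.0 if all(equal) else 0.0
        tukey_p = {ij: (1.0 if eq else 0.0) for ij, eq in zip(pair_idx, equal)}
        return anova_p, tukey_p, True
    n_tot = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    df_w = n_tot - k
    f_stat = (ssb / (k - 1)) / (ssw / df_w)
    anova_p = float(stats.f.sf(f_stat, k - 1, df_w))
    mse = ssw / df_w
    q = np.array(
        [
            abs(means[i] - means[j]) / np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            for i, j in pair_idx
        ]
    )
    p = stats.studentized_range.sf(q, k, df_w)
    tukey_p = {ij: float(pv) for ij, pv in zip(pair_idx, p)}
    return anova_p, tukey_p, False


def compare_groups(
    interactions: pd.DataFrame,
    design: Mapping | None = None,
    unit: str = "roi",
    alpha: float = ALPHA_DEFAULT,
    p_adjust: str = "none",
) -> pd.DataFrame:
    """ANOVA + Tukey HSD comparison of the normalized statistic across conditions.

    One row per (cn, pair, condition pair). ``unit="roi"`` uses the
    per-ROI normalized values as observations (the default convention
    here); ``unit="sample"`` first averages the ROIs of each sample.
    Hypotheses with fewer than two conditions having >= 2 observations
    are flagged ``untestable`` (p-values NA), never silently dropped.
    ``design`` optionally overrides the sample -> condition mapping
    carried in the table.
    """
    if unit not in ("roi", "sample"):
        raise ParameterError(f"unit must be 'roi' or 'sample', got '{unit}'")
    if p_adjust not in ("none", "bh"):
        raise ParameterError(f"p_adjust must be 'none' or 'bh', got '{p_adjust}'")
    df = interactions.copy()
    if design is not None:
        df["condition"] = df["sample_id"].map(dict(design))
    if df["condition"].nunique() < 2:
        raise ParameterError("need at least two conditions to compare")
    if unit == "sample":
        df = (
            df.groupby(["sample_id", "condition", "cn", "type_a", "type_b"],
                       observed=True)["normalized"]
            .mean()
            .reset_index()
        )

    rows = []
    for (cn, ta, tb), sub in df.groupby(["cn", "type_a", "type_b"], observed=True):
        by_cond = {
            c: g["normalized"].to_numpy(dtype=float)
            for c, g in sub.groupby("condition", observed=True)
        }
        usable = {c: v for c, v in by_cond.items() if len(v) >= 2}
        if len(usable) < 2:
            for ca, cb in itertools.combinations(sorted(by_cond), 2):
                rows.append((cn, ta, tb, ca, cb, np.nan, np.nan,
                             False, True, False))
            continue
        conds = sorted(usable)
        anova_p, tukey_p, degenerate = _anova_tukey([usable[c] for c in conds])
        for (i, j), p in tukey_p.items():
            rows.append((cn, ta, tb, conds[i], conds[j], anova_p, p,
                         False, False, degenerate))
        # condition pairs excluded for insufficient observations stay visible
        for ca, cb in itertools.combinations(sorted(by_cond), 2):
            if ca not in usable or cb not in usable:
                rows.append((cn, ta, tb, ca, cb, np.nan, np.nan,
                             False, True, False))
    out = pd.DataFrame(
        rows,
        columns=["cn", "type_a", "type_b", "group_a", "group_b",
                 "anova_p", "tukey_p", "significant", "untestable", "degenerate"],
    )
    if p_adjust == "bh":
        hyp = out.loc[~out["untestable"], ["cn", "type_a", "type_b", "anova_p"]]
        uniq = hyp.drop_duplicates(["cn", "type_a", "type_b"])
        adj = stats.false_discovery_control(uniq["anova_p"].to_numpy(), method="bh")
        lut = dict(zip(map(tuple, uniq[["cn", "type_a", "type_b"]].to_numpy()), adj))
        keys = list(map(tuple, out[["cn", "type_a", "type_b"]].to_numpy()))
        out["anova_p"] = [lut.get(k, np.nan) for k in keys]
    out["significant"] = (
        ~out["untestable"]
        & (out["anova_p"] < alpha)
        & (out["tukey_p"] < alpha)
    )
    return out


def filter_significant(
    comparisons: pd.DataFrame,
    reference: str,
    immune_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Keep significant condition pairs that involve the reference condition.

    Mirrors the reporting convention of showing only changes relative to
    a control group; optionally restrict to phenotype pairs involving at
    least one declared immune type (a display rule, not an inference
    rule).
    """
    present = set(comparisons["group_a"]) | set(comparisons["group_b"])
    if reference not in present:
        raise ParameterError(f"reference condition '{reference}' not present")
    mask = (
        ((comparisons["group_a"] == reference) | (comparisons["group_b"] == reference))
        & comparisons["significant"]
    )
    if immune_types is not None:
        immune = set(immune_types)
        mask &= comparisons["type_a"].isin(immune) | comparisons["type_b"].isin(immune)
    return comparisons.loc[mask].reset_index(drop=True)
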