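"""Cellular-neighborhood (CN) detection from spatial-graph composition.

Each cell is described by the phenotype composition of its 1-hop window
on the pruned Delaunay graph — the cell itself plus its graph neighbors,
as a normalized histogram over phenotypes (so an isolated cell is a
one-hot vector at its own type). The composition rows of all ROIs and
samples are clustered jointly with k-means (k-means++ init, multiple
restarts), which lets CN identities be compared across conditions and
timepoints. Fitted clusters are renamed CN1..CNk by descending size so
reports are stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ParameterError, StateError
from .graph import SpatialGraph
from .io import CellTable


def composition_vectors(
    table: CellTable, graphs: dict[str, SpatialGraph]
) -> pd.DataFrame:
    """Per-cell neighbor-composition matrix (rows sum to 1).

    Rows align with ``table.df``; columns are the phenotypes observed in
    the table, sorted. Every cell's window includes the cell itself, so
    no row is empty.
    """
    df = table.df
    if df["phenotype"].isna().any():
        raise StateError("phenotype labels not assigned for all cells")
    missing = set(df["roi_id"]) - set(graphs)
    if missing:
        raise StateError(f"no spatial graph for ROIs {sorted(missing)[:5]}")

    phenotypes = sorted(pd.unique(df["phenotype"]))
    code = {p: i for i, p in enumerate(phenotypes)}
    counts = np.zeros((len(df), len(phenotypes)), dtype=float)
    pheno_codes = df["phenotype"].map(code).to_numpy()
    rows = np.arange(len(df))
    counts[rows, pheno_codes] = 1.0  # the index cell itself

    pos_by_roi = {roi: sub.index.to_numpy() for roi, sub in df.groupby("roi_id", observed=True)}
    for roi, g in graphs.items():
        pos = pos_by_roi.get(roi)
        if pos is None or not len(g.edges):
            continue
        a = pos[g.edges[:, 0]]
        b = pos[g.edges[:, 1]]
        np.add.at(counts, (a, pheno_codes[b]), 1.0)
        np.add.at(counts, (b, pheno_codes[a]), 1.0)
    comp = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(comp, columns=phenotypes, index=df.index)


@dataclass
class NeighborhoodModel:
    """Fitted CN model: centroids in composition space and per-cell labels."""

    n_cn: int
    centroids: pd.DataFrame  # CN label x phenotype
    labels: np.ndarray       # per-cell "CN1".."CNk"
    seed: int
    n_init: int
    inertia: float


def detect_neighborhoods(
    comp: pd.DataFrame, n_cn: int = 6, seed: int = 0, n_init: int = 10
) -> NeighborhoodModel:
    """Cluster composition rows into ``n_cn`` cellular neighborhoods.

    k-means with k-means++ initialization and ``n_init`` restarts (best
    inertia kept). Should a cluster come back empty, the fit is retried
    with a shifted seed up to 5 times, then accepted with a warning.
    Labels are renamed CN1..CNk by descending cluster size.
    """
    n = len(comp)
    if n == 0:
        raise ParameterError("empty composition matrix")
    if n_cn >= n + 1 or n_cn > n:
        raise ParameterError(f"n_cn={n_cn} must be < n_cells={n}")
    X = comp.to_numpy(dtype=float)
    for attempt in range(6):
        km = KMeans(
            n_clusters=n_cn, init="k-means++", n_init=n_init,
            random_state=(seed + attempt) % 2**31,
        ).fit(X)
        if len(np.unique(km.labels_)) == n_cn:
            break
        if attempt == 5:
            warnings.warn("empty CN cluster persisted after 5 reseeds", stacklevel=2)
    sizes = np.bincount(km.labels_, minlength=n_cn)
    # descending size, ties broken by original cluster index for stability
    order = np.lexsort((np.arange(n_cn), -sizes))
    rank = np.empty(n_cn, dtype=int)
    rank[order] = np.arange(n_cn)
    labels = np.array([f"CN{rank[l] + 1}" for l in km.labels_])
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=[f"CN{i + 1}" for i in range(n_cn)],
        columns=comp.columns,
    )
    return NeighborhoodModel(
        n_cn=n_cn, centroids=centroids, labels=labels, seed=seed,
        n_init=n_init, inertia=float(km.inertia_),
    )


def assign_neighborhoods(table: CellTable, model: NeighborhoodModel) -> CellTable:
    """Write the fitted CN labels into the table's ``cn`` column."""
    return table.with_column("cn", model.labels)


@dataclass
class CnSummary:
    """Per-group CN size fractions and within-CN phenotype percentages."""

    cn_fractions: pd.DataFrame       # group x CN, percent of cells, rows sum 100
    phenotype_percent: pd.DataFrame  # (group, CN) x phenotype, rows sum 100


def cn_composition_summary(
    table: CellTable, by: Sequence[str] = ("condition",)
) -> CnSummary:
    """Summarize CN occupancy and per-CN cell-type composition per group.

    Groups with no cells in some CN report 0% for it rather than
    dropping the stratum.
    """
    df = table.df
    if df["cn"].isna().any():
        raise StateError("CN labels not assigned")
    by = list(by)
    sizes = df.groupby(by + ["cn"], observed=True).size().unstack("cn", fill_value=0)
    cn_fractions = sizes.div(sizes.sum(axis=1), axis=0) * 100.0
    ph = (
        df.groupby(by + ["cn", "phenotype"], observed=True)
        .size()
        .unstack("phenotype", fill_value=0)
    )
    totals = ph.sum(axis=1)
    phenotype_percent = ph.div(totals.where(totals > 0, 1.0), axis=0) * 100.0
    return CnSummary(cn_fractions, phenotype_percent)
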