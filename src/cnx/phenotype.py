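"""Marker normalization and Phenograph-style phenotype clustering.

Cells are clustered in marker space by the shared-nearest-neighbor
community-detection scheme used throughout cytometry: a k-nearest-neighbor
graph (Euclidean, k = 50 by default), edges reweighted by the Jaccard
overlap of the two endpoints' neighbor sets, then modularity maximization
with the Louvain method. Cluster-profile z-score matrices summarize mean
marker expression per cluster for manual cell-type annotation; the
cluster -> cell-type mapping itself is user-supplied expert curation,
never inferred.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, ParameterError, StateError
from .io import CellTable

UNDEFINED = "undefined"


def normalize_markers(
    table: CellTable,
    method: str = "asinh",
    cofactor: float = 5.0,
    clip_quantile: float = 0.999,
) -> CellTable:
    """Normalize the marker matrix; returns a new table.

    The default chain is the standard IMC preprocessing: inverse
    hyperbolic sine with a cofactor (``asinh(x / cofactor)``), per-marker
    clipping at the ``clip_quantile`` quantile to tame hot pixels, then
    per-marker min-max scaling to [0, 1]. Columns that are constant after
    transformation map to all-zero. ``method="none"`` returns a copy.
    """
    if method == "none":
        return table.copy()
    if method != "asinh":
        raise ConfigError(f"unknown normalization method '{method}'")
    X = table.markers().to_numpy(dtype=float)
    X = np.arcsinh(X / float(cofactor))
    if len(X):
        hi = np.quantile(X, clip_quantile, axis=0)
        X = np.minimum(X, hi)
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        const = span <= 0
        span[const] = 1.0
        X = (X - lo) / span
        X[:, const] = 0.0
    return table.with_markers(X)


@dataclass
class PhenotypeModel:
    """Result of phenotype clustering.

    ``labels`` are contiguous integer cluster ids starting at 1, one per
    cell in the order of the table that was clustered.
    """

    k_nn: int
    seed: int
    labels: np.ndarray
    n_clusters: int
    type_map: dict[int, str] = field(default_factory=dict)


def _jaccard_knn_graph(X: np.ndarray, k: int) -> ig.Graph:
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    A = sparse.csr_matrix(
        (np.ones(n * k, dtype=np.float64), (rows, idx.ravel())), shape=(n, n)
    )
    A.data[:] = 1.0  # collapse duplicate entries
    inter = A @ A.T
    cand = A.maximum(A.T)  # undirected candidate edges
    cand = sparse.triu(cand, k=1).tocoo()
    i, j = cand.row, cand.col
    shared = np.asarray(inter[i, j]).ravel()
    union = 2.0 * k - shared
    w = shared / union
    keep = w > 0
    g = ig.Graph(n=n, edges=list(zip(i[keep], j[keep])))
    g.es["weight"] = w[keep].tolist()
    return g


def cluster_phenotypes(
    table: CellTable, k_nn: int = 50, seed: int = 0
) -> PhenotypeModel:
    """Cluster cells in (normalized) marker space.

    Builds the Jaccard-weighted kNN graph and maximizes modularity with
    Louvain. Deterministic given (data, k_nn, seed): the Louvain node
    order is fixed by seeding the random number generator.
    """
    n = table.n_cells
    if k_nn >= n:
        raise ParameterError(f"k_nn={k_nn} must be smaller than n_cells={n}")
    X = table.markers().to_numpy(dtype=float)
    g = _jaccard_knn_graph(X, k_nn)
    state = random.getstate()
    try:
        random.seed(seed)  # igraph's Louvain draws its vertex order from here
        part = g.community_multilevel(weights="weight")
    finally:
        random.setstate(state)
    labels = np.asarray(part.membership, dtype=int) + 1
    return PhenotypeModel(
        k_nn=k_nn, seed=seed, labels=labels, n_clusters=int(labels.max())
    )


@dataclass
class ZScoreProfile:
    """Cluster x marker z-score matrix with degenerate columns flagged."""

    zscores: pd.DataFrame
    constant_markers: list[str]


def cluster_profile_zscores(table: CellTable, model: PhenotypeModel) -> ZScoreProfile:
    """Z-score of per-cluster mean expression, per marker.

    Entry (c, m) standardizes cluster c's mean of marker m across the
    cluster means (ddof = 1). Markers whose cluster means are identical
    are reported as an all-zero column and listed in
    ``constant_markers``.
    """
    if model.n_clusters < 2:
        raise StateError("z-scores need at least 2 clusters")
    means = (
        table.markers()
        .groupby(pd.Series(model.labels, index=table.df.index, name="cluster"))
        .mean()
    )
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    const = sd <= 0
    sd = sd.where(~const, 1.0)
    z = (means - mu) / sd
    z.loc[:, const] = 0.0
    return ZScoreProfile(z, list(means.columns[const]))


def assign_cell_types(
    table: CellTable, model: PhenotypeModel, mapping: dict[int, str] | None = None
) -> CellTable:
    """Fill the phenotype column from a cluster -> cell-type mapping.

    Clusters absent from the mapping become ``"undefined"`` (cell type
    could not be characterized); mapping entries that reference
    nonexistent cluster ids produce a warning and are ignored.
    """
    mapping = dict(mapping or {})
    observed = set(range(1, model.n_clusters + 1))
    unknown = sorted(set(mapping) - observed)
    if unknown:
        warnings.warn(f"mapping references nonexistent cluster ids {unknown}",
                      stacklevel=2)
    names = [mapping.get(c, UNDEFINED) for c in model.labels]
    model.type_map = {c: mapping.get(c, UNDEFINED) for c in sorted(observed)}
    return table.with_column("phenotype", names)
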