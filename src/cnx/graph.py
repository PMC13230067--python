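"""Per-ROI spatial interaction graphs from pruned Delaunay triangulation.

Cell-cell contacts are predicted by triangulating the cell centroids of
one ROI (Delaunay) and keeping only edges no longer than ``max_dist``
micrometres (default 20, the scale of directly touching cells). ROIs are
disjoint images, so no edges ever cross ROIs.

Coincident centroids (segmentation artefacts) would make the
triangulation ill-defined; they are separated by a deterministic, seeded
jitter of 1e-6 um before triangulating, and edge lengths are reported
from the original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateInputError, IntegrityError
from .io import CellTable

JITTER_EPS = 1e-6  # um


@dataclass
class SpatialGraph:
    """Undirected pruned-Delaunay graph of one ROI.

    ``edges`` is an (m, 2) array of indices into ``cell_ids`` with
    ``edges[:, 0] < edges[:, 1]``; ``lengths`` holds the matching
    Euclidean edge lengths in micrometres (all <= ``max_dist``).
    """

    roi_id: str
    cell_ids: np.ndarray
    edges: np.ndarray
    lengths: np.ndarray
    max_dist: float
    n_jittered: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Adjacency as index arrays, one per cell (isolated cells -> empty)."""
        adj: list[list[int]] = [[] for _ in range(self.n_cells)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return [np.asarray(v, dtype=int) for v in adj]

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_id,
                "cell_a": self.cell_ids[self.edges[:, 0]],
                "cell_b": self.cell_ids[self.edges[:, 1]],
                "length_um": self.lengths,
            }
        )


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points)
    s = tri.simplices
    e = np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def build_delaunay_graph(
    points: np.ndarray,
    cell_ids=None,
    roi_id: str = "",
    max_dist: float = 20.0,
    seed: int = 0,
    allow_degenerate: bool = False,
) -> SpatialGraph:
    """Triangulate one ROI's centroids and prune edges longer than ``max_dist``.

    Fewer than 3 points, or a fully collinear set, cannot be
    triangulated: this raises :class:`DegenerateInputError` unless
    ``allow_degenerate`` is set, in which case an edgeless graph is
    returned (every cell isolated).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise IntegrityError("points must be an (n, 2) array")
    if not np.isfinite(points).all():
        raise IntegrityError("non-finite coordinates")
    n = len(points)
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)

    empty = SpatialGraph(
        roi_id=roi_id,
        cell_ids=cell_ids,
        edges=np.empty((0, 2), dtype=int),
        lengths=np.empty(0, dtype=float),
        max_dist=float(max_dist),
    )
    n_distinct = len(np.unique(points, axis=0))
    if n_distinct < 3:
        if allow_degenerate:
            return empty
        raise DegenerateInputError(
            f"need >= 3 distinct points, got {n_distinct} (roi '{roi_id}')"
        )

    # deterministic jitter of exact duplicates so qhull sees distinct sites
    tri_points = points
    n_jittered = 0
    _, first = np.unique(points, axis=0, return_index=True)
    dup_mask = np.ones(n, dtype=bool)
    dup_mask[first] = False
    if dup_mask.any():
        rng = np.random.default_rng(seed)
        tri_points = points.copy()
        k = int(dup_mask.sum())
        theta = rng.uniform(0, 2 * np.pi, size=k)
        r = JITTER_EPS * (1 + rng.uniform(size=k))
        tri_points[dup_mask] += np.c_[r * np.cos(theta), r * np.sin(theta)]
        n_jittered = k

    try:
        edges = _delaunay_edges(tri_points)
    except QhullError:
        if allow_degenerate:
            return empty
        raise DegenerateInputError(f"degenerate geometry in roi '{roi_id}'") from None

    lengths = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
    keep = lengths <= float(max_dist)
    return SpatialGraph(
        roi_id=roi_id,
        cell_ids=cell_ids,
        edges=edges[keep],
        lengths=lengths[keep],
        max_dist=float(max_dist),
        n_jittered=n_jittered,
    )


def build_roi_graphs(
    table: CellTable, max_dist: float = 20.0, seed: int = 0,
    allow_degenerate: bool = True,
) -> dict[str, SpatialGraph]:
    """Build one pruned-Delaunay graph per ROI of a cell table.

    Degenerate ROIs (< 3 distinct centroids) yield edgeless graphs by
    default so that tiny ROIs survive as isolated cells rather than
    aborting a whole study.
    """
    graphs: dict[str, SpatialGraph] = {}
    for k, (roi, sub) in enumerate(table.df.groupby("roi_id", observed=True, sort=True)):
        graphs[roi] = build_delaunay_graph(
            sub[["x", "y"]].to_numpy(dtype=float),
            cell_ids=sub["cell_id"].to_numpy(),
            roi_id=roi,
            max_dist=max_dist,
            seed=(seed + k) % 2**31,
            allow_degenerate=allow_degenerate,
        )
    return graphs


def degree_summary(graph: SpatialGraph) -> pd.DataFrame:
    """Per-cell degree; isolated cells (all incident edges pruned) get 0."""
    deg = np.zeros(graph.n_cells, dtype=int)
    idx, cnt = np.unique(graph.edges, return_counts=True)
    deg[idx] = cnt
    return pd.DataFrame(
        {"roi_id": graph.roi_id, "cell_id": graph.cell_ids, "degree": deg}
    )


def edge_list_table(graphs: dict[str, SpatialGraph]) -> pd.DataFrame:
    """Concatenate per-ROI edge lists into one long table."""
    parts = [g.edge_table() for g in graphs.values()]
    if not parts:
        return pd.DataFrame(columns=["roi_id", "cell_a", "cell_b", "length_um"])
    return pd.concat(parts, ignore_index=True)
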