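"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take the slow, definitional route: the Delaunay oracle
enumerates all point triples and tests the empty-circumcircle property
directly (O(n^4)); the Tukey oracle is scipy's own HSD implementation,
checked against the package's studentized-range computation.
"""

from itertools import combinations

import numpy as np


def brute_force_delaunay_edges(points: np.ndarray, max_dist: float) -> set:
    """Edge set {(i, j), i < j} of the Delaunay triangulation, by definition.

    A triangle belongs to the triangulation iff no other point lies
    strictly inside its circumcircle; the triangulation's edges are the
    union of such triangles' edges. Assumes general position (no 4
    cocircular points, no 3 collinear forming a candidate triangle).
    Edges longer than ``max_dist`` are filtered out afterwards.
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
    ok = np.abs(d) > 1e-12  # drop collinear triples
    tri, A, B, C, d = tri[ok], A[ok], B[ok], C[ok], d[ok]
    a2 = (A**2).sum(1)
    b2 = (B**2).sum(1)
    c2 = (C**2).sum(1)
    ux = (a2 * (B[:, 1] - C[:, 1]) + b2 * (C[:, 1] - A[:, 1]) + c2 * (A[:, 1] - B[:, 1])) / d
    uy = (a2 * (C[:, 0] - B[:, 0]) + b2 * (A[:, 0] - C[:, 0]) + c2 * (B[:, 0] - A[:, 0])) / d
    centers = np.c_[ux, uy]
    r2 = ((A - centers) ** 2).sum(1)
    dist2 = ((P[None, :, :] - centers[:, None, :]) ** 2).sum(2)  # (n_tri, n)
    inside = dist2 < r2[:, None] * (1.0 - 1e-9)
    empty = ~inside.any(axis=1)
    edges = set()
    for i, j, k in tri[empty]:
        for e in ((i, j), (i, k), (j, k)):
            e = (min(e), max(e))
            if np.linalg.norm(P[e[0]] - P[e[1]]) <= max_dist:
                edges.add(e)
    return edges


def tukey_hsd_reference(groups):
    """Tukey HSD p-values per group pair from scipy's own implementation."""
    from scipy import stats

    res = stats.tukey_hsd(*groups)
    k = len(groups)
    return {(i, j): float(res.pvalue[i, j]) for i, j in combinations(range(k), 2)}
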