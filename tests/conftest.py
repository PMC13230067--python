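import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cnx import CellTable
from cnx.io import STANDARD_COLUMNS


def make_table(rows, marker_names=("m1", "m2", "m3")):
    """Build a CellTable from (cell_id, roi_id, sample_id, condition, x, y,
    phenotype, *markers) tuples; roi_class unclassified, cn unset."""
    recs = []
    for cell, roi, sample, cond, x, y, pheno, *markers in rows:
        recs.append(
            {
                "cell_id": cell, "roi_id": roi, "sample_id": sample,
                "condition": cond, "roi_class": "unclassified",
                "x": float(x), "y": float(y), "phenotype": pheno, "cn": None,
                **dict(zip(marker_names, map(float, markers))),
            }
        )
    df = pd.DataFrame(recs, columns=list(STANDARD_COLUMNS) + list(marker_names))
    return CellTable(df, list(marker_names))


@pytest.fixture
def toy_table():
    """Six cells, two ROIs, one sample, three markers."""
    rows = [
        ("c1", "r1", "s1", "control", 0, 0, "A", 1, 0, 0),
        ("c2", "r1", "s1", "control", 10, 0, "A", 1, 0, 0),
        ("c3", "r1", "s1", "control", 0, 10, "B", 0, 1, 0),
        ("c4", "r2", "s1", "control", 0, 0, "B", 0, 1, 0),
        ("c5", "r2", "s1", "control", 5, 5, "A", 1, 0, 0),
        ("c6", "r2", "s1", "control", 10, 0, "B", 0, 0, 1),
    ]
    return make_table(rows)


@pytest.fixture
def blob_table():
    """Three well-separated Gaussian blobs in 2-marker space (n = 300)."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    X = np.concatenate(
        [c + 0.01 * rng.standard_normal((100, 2)) for c in centers]
    )
    truth = np.repeat([0, 1, 2], 100)
    rows = [
        (f"c{i}", "r1", "s1", "control", rng.uniform(0, 100), rng.uniform(0, 100),
         None, X[i, 0], X[i, 1])
        for i in range(300)
    ]
    table = make_table(rows, marker_names=("mA", "mB"))
    return table, truth
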