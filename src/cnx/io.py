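"""Reading, validating and summarizing per-cell spatial tables.

The canonical input is a delimited text file (comma or tab, auto-detected)
with one row per segmented cell: identifiers (cell, ROI, sample), a
condition label, centroid coordinates in micrometres, and one column per
marker. :class:`CellTable` wraps a validated :class:`pandas.DataFrame`
with a fixed set of standard columns plus the marker columns.

Coordinates are treated as micrometres throughout; if the source file is
in pixels, set ``pixel_size_um`` in the schema and coordinates are scaled
at read time so that downstream distance thresholds stay unit-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, StateError

#: standard (non-marker) columns of a cell table, in canonical order
STANDARD_COLUMNS = (
    "cell_id",
    "roi_id",
    "sample_id",
    "condition",
    "roi_class",
    "x",
    "y",
    "phenotype",
    "cn",
)

ROI_CLASSES = ("epithelial", "immune", "mixed", "unclassified")

#: default schema: file columns already use the standard names
DEFAULT_SCHEMA: dict = {
    "cell_id": "cell_id",
    "roi_id": "roi_id",
    "sample_id": "sample_id",
    "condition": "condition",
    "x": "x",
    "y": "y",
}


@dataclass
class CellTable:
    """A validated per-cell table for one study.

    Parameters
    ----------
    df
        One row per cell. Contains all ``STANDARD_COLUMNS`` plus one
        numeric column per marker. ``phenotype``/``cn`` may be all-NA
        until the corresponding pipeline stage has run.
    marker_names
        Ordered marker column names.
    """

    df: pd.DataFrame
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_cell_table(self.df, self.marker_names)
        self.df = self.df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def roi_ids(self) -> list:
        return list(pd.unique(self.df["roi_id"]))

    @property
    def group_design(self) -> dict:
        """Map sample_id -> condition."""
        pairs = self.df[["sample_id", "condition"]].drop_duplicates()
        return dict(zip(pairs["sample_id"], pairs["condition"]))

    def markers(self) -> pd.DataFrame:
        return self.df[self.marker_names]

    def with_markers(self, values: np.ndarray) -> "CellTable":
        """Return a copy with the marker matrix replaced (same shape)."""
        df = self.df.copy()
        df[self.marker_names] = np.asarray(values, dtype=float)
        return CellTable(df, list(self.marker_names))

    def with_column(self, name: str, values) -> "CellTable":
        df = self.df.copy()
        df[name] = np.asarray(values)
        return CellTable(df, list(self.marker_names))

    def copy(self) -> "CellTable":
        return CellTable(self.df.copy(), list(self.marker_names))


def validate_cell_table(df: pd.DataFrame, marker_names: Sequence[str]) -> None:
    for col in STANDARD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing standard column '{col}'")
    for m in marker_names:
        if m not in df.columns:
            raise SchemaError(f"missing marker column '{m}'")
    if len(df) == 0:
        return
    dup = df.duplicated(subset=["roi_id", "cell_id"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise IntegrityError(f"duplicate (roi_id, cell_id) pairs at rows {rows}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        rows = df.index[np.flatnonzero(bad)].tolist()[:10]
        raise IntegrityError(f"non-finite coordinates at rows {rows}")
    # a sample must map to exactly one condition
    per_sample = df.groupby("sample_id", observed=True)["condition"].nunique()
    if (per_sample > 1).any():
        bad_samples = per_sample.index[per_sample > 1].tolist()
        raise IntegrityError(
            f"samples mapped to more than one condition: {bad_samples}"
        )


def _detect_delimiter(path: Path) -> str:
    header = Path(path).open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_cell_table(path, schema: Mapping | None = None) -> CellTable:
    """Read and validate a delimited-text cell table.

    ``schema`` maps standard names to file column names and lists the
    marker columns::

        {"cell_id": "ObjectId", "roi_id": "ROI", "sample_id": "mouse",
         "condition": "timepoint", "x": "X_centroid", "y": "Y_centroid",
         "markers": ["CD3", "CD8a", ...],      # omit -> all other numeric cols
         "roi_class": "roi_type",              # optional
         "pixel_size_um": 1.0}                 # optional, scales x/y

    Marker values are coerced to nonnegative floats; small negatives
    (spillover-compensated data) are clamped to zero with a warning, and
    rows whose coordinates or marker values cannot be coerced raise an
    :class:`IntegrityError` naming the offending rows.
    """
    schema = dict(DEFAULT_SCHEMA) | dict(schema or {})
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_delimiter(path))

    mandatory = ["cell_id", "roi_id", "sample_id", "condition", "x", "y"]
    for key in mandatory:
        col = schema.get(key)
        if col is None or col not in raw.columns:
            raise SchemaError(f"input file lacks column '{col}' for field '{key}'")

    marker_cols = schema.get("markers")
    if marker_cols is None:
        used = {schema[k] for k in mandatory}
        used |= {schema.get("roi_class"), schema.get("phenotype"), schema.get("cn")}
        marker_cols = [
            c for c in raw.columns
            if c not in used and pd.api.types.is_numeric_dtype(raw[c])
        ]
    missing = [m for m in marker_cols if m not in raw.columns]
    if missing:
        raise SchemaError(f"marker columns not in file: {missing}")

    df = pd.DataFrame(
        {
            "cell_id": raw[schema["cell_id"]].astype(str),
            "roi_id": raw[schema["roi_id"]].astype(str),
            "sample_id": raw[schema["sample_id"]].astype(str),
            "condition": raw[schema["condition"]].astype(str),
        }
    )
    rc = schema.get("roi_class")
    if rc is not None and rc in raw.columns:
        df["roi_class"] = raw[rc].astype(str).where(raw[rc].notna(), "unclassified")
    else:
        df["roi_class"] = "unclassified"

    for axis in ("x", "y"):
        coerced = pd.to_numeric(raw[schema[axis]], errors="coerce")
        bad = coerced.isna() | ~np.isfinite(coerced.to_numpy(dtype=float))
        if bad.any():
            rows = raw.index[bad].tolist()[:10]
            raise IntegrityError(
                f"column '{schema[axis]}' has non-finite/unparseable values at rows {rows}"
            )
        df[axis] = coerced.astype(float)
    px = float(schema.get("pixel_size_um") or 1.0)
    if px != 1.0:
        df["x"] *= px
        df["y"] *= px

    markers = pd.DataFrame(index=raw.index)
    for m in marker_cols:
        coerced = pd.to_numeric(raw[m], errors="coerce")
        if coerced.isna().any():
            rows = raw.index[coerced.isna()].tolist()[:10]
            raise IntegrityError(
                f"marker column '{m}' has unparseable values at rows {rows}"
            )
        markers[m] = coerced.astype(float)
    neg = (markers.to_numpy() < 0).sum()
    if neg:
        warnings.warn(
            f"{neg} negative marker intensities clamped to zero", stacklevel=2
        )
        markers = markers.clip(lower=0.0)

    for key in ("phenotype", "cn"):
        col = schema.get(key)
        if col is not None and col in raw.columns:
            df[key] = raw[col].astype(str).where(raw[col].notna(), None)
        else:
            df[key] = pd.Series([None] * len(raw), dtype=object)

    out = pd.concat([df, markers], axis=1)
    return CellTable(out[list(STANDARD_COLUMNS) + marker_cols], list(marker_cols))


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table as delimited text (TSV if the suffix is .tsv)."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    table.df.to_csv(path, sep=sep, index=False)


@dataclass
class FrequencySummary:
    """Cell-type frequency tables at two levels of aggregation.

    ``pooled`` treats all cells of a group as one pool; ``sample_mean``
    averages per-sample percentages, so a small sample counts as much as
    a large one (the "mean percentage across samples" convention used for
    bar-graph summaries). ``per_sample`` holds the underlying
    sample-level percentages.
    """

    pooled: pd.DataFrame
    per_sample: pd.DataFrame
    sample_mean: pd.DataFrame


def _percentages(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    counts = (
        df.groupby(keys + ["phenotype"], observed=True)
        .size()
        .unstack("phenotype", fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def summarize_cell_frequencies(
    table: CellTable, by: Sequence[str] = ("condition",)
) -> FrequencySummary:
    """Percentage of each phenotype per group, pooled and per sample."""
    df = table.df
    if df["phenotype"].isna().all():
        raise StateError("phenotype labels not assigned")
    by = list(by)
    pooled = _percentages(df, by)
    per_sample = _percentages(df, by + ["sample_id"])
    sample_mean = per_sample.groupby(level=by, observed=True).mean()
    return FrequencySummary(pooled, per_sample, sample_mean)


def summarize_roi_classes(table: CellTable) -> pd.DataFrame:
    """Per-condition ROI-class counts and percentages.

    One ROI contributes once (its class is constant across its cells);
    unclassified ROIs appear as their own category.
    """
    rois = table.df[["condition", "roi_id", "roi_class"]].drop_duplicates("roi_id")
    counts = (
        rois.groupby(["condition", "roi_class"], observed=True)
        .size()
        .unstack("roi_class", fill_value=0)
    )
    for cls in ROI_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[list(ROI_CLASSES)]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    out = pd.concat({"count": counts, "percent": pct}, axis=1)
    return out


def to_anndata(table: CellTable):
    """Convenience adapter to the annotated-matrix container (AnnData).

    Markers become ``X``, standard columns go to ``obs`` and coordinates
    to ``obsm["spatial"]``. Requires the optional ``anndata`` package.
    """
    import anndata as ad

    obs = table.df[[c for c in STANDARD_COLUMNS]].copy()
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=table.markers().to_numpy(dtype=float),
        obs=obs,
        var=pd.DataFrame(index=table.marker_names),
    )
    adata.obsm["spatial"] = table.df[["x", "y"]].to_numpy(dtype=float)
    return adata


def from_anndata(adata) -> CellTable:
    """Inverse of :func:`to_anndata`."""
    df = adata.obs[[c for c in STANDARD_COLUMNS if c in adata.obs.columns]].copy()
    for col in STANDARD_COLUMNS:
        if col not in df.columns:
            df[col] = "unclassified" if col == "roi_class" else None
    if "spatial" in adata.obsm:
        df[["x", "y"]] = np.asarray(adata.obsm["spatial"], dtype=float)
    markers = pd.DataFrame(
        np.asarray(adata.X, dtype=float), columns=list(adata.var_names), index=df.index
    )
    out = pd.concat([df[list(STANDARD_COLUMNS)], markers], axis=1)
    return CellTable(out.reset_index(drop=True), list(adata.var_names))
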