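"""End-to-end orchestration: validate -> phenotype -> graph -> CN -> interactions.

One :class:`RunConfig` drives the whole analysis; a single global seed
derives a distinct deterministic seed per stage, all parameters are
echoed into a YAML run manifest together with per-stage row counts, and
rerunning with identical config and inputs reproduces identical output
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import CnxError, PipelineError
from .graph import build_roi_graphs, edge_list_table
from .interactions import compare_groups, count_cn_interactions, filter_significant
from .io import CellTable, read_cell_table, write_cell_table
from .neighborhoods import (
    assign_neighborhoods,
    cn_composition_summary,
    composition_vectors,
    detect_neighborhoods,
)
from .phenotype import (
    assign_cell_types,
    cluster_phenotypes,
    cluster_profile_zscores,
    normalize_markers,
)
from .simulate import SyntheticConfig, config_to_dict, generate_tissue


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    return (seed * 100_003 + 7919 * stage_index + 1) % 2**31


@dataclass
class RunConfig:
    """Parameters for a full pipeline run."""

    input_path: str | None = None
    schema: dict = field(default_factory=dict)
    simulate: SyntheticConfig | None = None
    k_nn: int = 50
    cofactor: float = 5.0
    max_dist: float = 20.0
    n_cn: int = 6
    seed: int = 0
    type_map: dict[int, str] | None = None
    reference: str = "control"
    unit: str = "roi"
    alpha: float = 0.05
    out_dir: str = "cnx_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import Attraction, Domain

            sim["domains"] = [Domain(**d) for d in sim.get("domains", [])] or None
            if sim["domains"] is None:
                sim.pop("domains")
            sim["attraction"] = [Attraction(**a) for a in sim.get("attraction", [])]
            if "roi_size" in sim:
                sim["roi_size"] = tuple(sim["roi_size"])
            if "conditions" in sim:
                sim["conditions"] = tuple(sim["conditions"])
            cfg.simulate = SyntheticConfig(**sim)
        return cfg


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage in order and write all artifacts to ``out_dir``.

    Returns the map of artifact names to paths. Any stage failure is
    re-raised as :class:`PipelineError` carrying the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    def _stage(name: str, fn):
        try:
            return fn()
        except CnxError as e:
            raise PipelineError(name, str(e)) from e

    # -- input ----------------------------------------------------------------
    def _load() -> CellTable:
        if config.simulate is not None:
            sim = config.simulate
            table, truth = generate_tissue(sim)
            truth.df.to_csv(out / "truth.csv", index=False)
            artifacts["truth"] = out / "truth.csv"
            return table
        if config.input_path is None:
            raise CnxError("config provides neither input_path nor simulate")
        table = read_cell_table(config.input_path, config.schema)
        if table.n_cells == 0:
            raise CnxError("input table is empty")
        return table

    table = _stage("cell_table_io", _load)
    counts["cells"] = table.n_cells

    # -- phenotyping ----------------------------------------------------------
    def _phenotype() -> CellTable:
        normed = normalize_markers(table, cofactor=config.cofactor)
        model = cluster_phenotypes(normed, k_nn=config.k_nn,
                                   seed=stage_seed(config.seed, 1))
        mapping = config.type_map or {
            c: f"C{c}" for c in range(1, model.n_clusters + 1)
        }
        profile = cluster_profile_zscores(normed, model)
        profile.zscores.to_csv(out / "cluster_zscores.csv")
        artifacts["zscores"] = out / "cluster_zscores.csv"
        counts["phenotype_clusters"] = model.n_clusters
        return assign_cell_types(table, model, mapping)

    if table.df["phenotype"].notna().all():
        labeled = table  # precomputed phenotype labels supplied in the input
        counts["phenotype_clusters"] = int(table.df["phenotype"].nunique())
    else:
        labeled = _stage("phenotyping", _phenotype)

    # -- spatial graph --------------------------------------------------------
    graphs = _stage(
        "spatial_graph",
        lambda: build_roi_graphs(labeled, max_dist=config.max_dist,
                                 seed=stage_seed(config.seed, 2)),
    )
    edges = edge_list_table(graphs)
    edges.to_csv(out / "edges.csv", index=False)
    artifacts["edges"] = out / "edges.csv"
    counts["edges"] = len(edges)

    # -- neighborhoods --------------------------------------------------------
    def _neighborhoods() -> CellTable:
        comp = composition_vectors(labeled, graphs)
        model = detect_neighborhoods(comp, n_cn=config.n_cn,
                                     seed=stage_seed(config.seed, 3))
        model.centroids.to_csv(out / "cn_centroids.csv")
        artifacts["cn_centroids"] = out / "cn_centroids.csv"
        return assign_neighborhoods(labeled, model)

    with_cn = _stage("neighborhoods", _neighborhoods)
    summary = cn_composition_summary(with_cn)
    summary.cn_fractions.to_csv(out / "cn_fractions.csv")
    summary.phenotype_percent.to_csv(out / "cn_phenotype_percent.csv")
    artifacts["cn_fractions"] = out / "cn_fractions.csv"
    artifacts["cn_phenotype_percent"] = out / "cn_phenotype_percent.csv"
    write_cell_table(with_cn, out / "cells.csv")
    artifacts["cells"] = out / "cells.csv"

    # -- interactions ---------------------------------------------------------
    def _interactions():
        inter = count_cn_interactions(with_cn, graphs)
        comp = compare_groups(inter, unit=config.unit, alpha=config.alpha)
        sig = filter_significant(comp, reference=config.reference)
        return inter, comp, sig

    inter, comparisons, significant = _stage("interactions", _interactions)
    inter.to_csv(out / "interactions.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    significant.to_csv(out / "significant.csv", index=False)
    artifacts["interactions"] = out / "interactions.csv"
    artifacts["comparisons"] = out / "comparisons.csv"
    artifacts["significant"] = out / "significant.csv"
    counts["interaction_rows"] = len(inter)
    counts["comparison_rows"] = len(comparisons)
    counts["significant_rows"] = len(significant)

    # -- manifest -------------------------------------------------------------
    manifest = {
        "cnx_version": __version__,
        "parameters": {
            "input_path": config.input_path,
            "schema": dict(config.schema),
            "k_nn": config.k_nn,
            "cofactor": config.cofactor,
            "max_dist": config.max_dist,
            "n_cn": config.n_cn,
            "reference": config.reference,
            "unit": config.unit,
            "alpha": config.alpha,
        },
        "seed": config.seed,
        "stage_seeds": {f"stage_{i}": stage_seed(config.seed, i) for i in range(4)},
        "simulate": config_to_dict(config.simulate) if config.simulate else None,
        "row_counts": counts,
        "jittered_points": {r: g.n_jittered for r, g in graphs.items()
                            if g.n_jittered},
        "bridging_edges": int(inter.attrs.get("n_bridging_edges", 0)),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    artifacts["manifest"] = out / "manifest.yaml"
    return artifacts
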