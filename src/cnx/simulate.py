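"""Synthetic multi-ROI tissues with planted ground truth.

The generator emulates the statistical structure of segmented IMC data
from gut tissue: several conditions (e.g. control plus disease
timepoints), a few mice or patients per condition, a few ROIs per
sample. Each ROI rectangle is partitioned into spatially contiguous
domains of distinct phenotype composition — the planted cellular
neighborhoods — either as parallel strips ("blocks") or seeded Voronoi
regions ("blobs"). Cells arrive as a homogeneous Poisson process,
phenotypes are drawn i.i.d. from the domain composition, and marker
intensities per phenotype follow a log-normal model (heavy-tailed,
positive, like ion-count IMC intensities).

Pairwise attraction can be planted per condition: a fraction theta of
the cells of type B is relocated to within a small disc (default 10 um)
of a uniformly chosen type-A cell of the same domain, which raises the
expected A-B Delaunay edge count monotonically in theta. theta = 0
relocates nobody, so the null is exactly the no-attraction process.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, IntegrityError, StateError
from .io import CellTable, STANDARD_COLUMNS


@dataclass
class Domain:
    """A contiguous tissue compartment with its phenotype composition."""

    name: str
    composition: dict[str, float]


@dataclass
class Attraction:
    """Planted attraction: in ``condition``, pull type-B cells toward type A."""

    condition: str
    type_a: str
    type_b: str
    strength: float  # theta in [0, 1]: fraction of B cells relocated


def default_domains() -> list[Domain]:
    """Three gut-like compartments with crisp, well-separated compositions.

    The epithelium is dominated by epithelial cells with a minority of
    intraepithelial CD8 T cells; the lamina propria is immune-rich with
    vasculature; the muscularis is smooth muscle with vessels. Pairwise
    L1 distances between the composition vectors are 1.5-1.9.
    """
    return [
        Domain("epithelium", {"epithelial": 0.85, "CD8T": 0.10, "macrophage": 0.05}),
        Domain("lamina_propria",
               {"CD8T": 0.40, "macrophage": 0.35, "VEC": 0.15, "epithelial": 0.10}),
        Domain("muscularis", {"SMC": 0.70, "VEC": 0.20, "macrophage": 0.10}),
    ]


def default_marker_model() -> dict[str, dict[str, float]]:
    """Log-scale marker means per phenotype: one bright canonical marker each."""
    markers = ["Ecad", "CD8a", "CD68", "aSMA", "CD31", "Ki67"]
    canonical = {
        "epithelial": "Ecad", "CD8T": "CD8a", "macrophage": "CD68",
        "SMC": "aSMA", "VEC": "CD31",
    }
    model = {}
    for ph, bright in canonical.items():
        model[ph] = {m: (3.0 if m == bright else 0.0) for m in markers}
        model[ph]["Ki67"] = 0.5  # dim shared proliferation marker
    return model


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults emulate the study design scale.

    Three conditions (a control plus two disease stages), three mice per
    condition and three ROIs per mouse mirror the usual IMC design.
    ``cell_density`` of 0.008 cells/um^2 is a typical segmented-cell
    density for gut tissue; at the default 400 x 400 um ROI that is
    ~1,300 cells per ROI.
    """

    conditions: Sequence[str] = ("control", "early", "late")
    samples_per_condition: int = 3
    rois_per_sample: int = 3
    roi_size: tuple[float, float] = (400.0, 400.0)
    cell_density: float = 0.008
    domains: list[Domain] = field(default_factory=default_domains)
    spatial_layout: str = "blocks"  # or "blobs"
    marker_model: dict[str, dict[str, float]] = field(default_factory=default_marker_model)
    marker_sigma: float = 0.35
    attraction: list[Attraction] = field(default_factory=list)
    attraction_radius: float = 10.0  # um
    blob_seeds_per_domain: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_condition < 1 or self.rois_per_sample < 1:
            raise ConfigError("sample and ROI counts must be positive")
        if self.spatial_layout not in ("blocks", "blobs"):
            raise ConfigError(f"unknown spatial_layout '{self.spatial_layout}'")
        for d in self.domains:
            total = sum(d.composition.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in d.composition.values()):
                raise ConfigError(
                    f"domain '{d.name}' composition must be a distribution (sums to {total})"
                )
        area = self.roi_size[0] * self.roi_size[1]
        if self.cell_density * area < 10:
            raise ConfigError("expected cells per ROI must be >= 10")
        for a in self.attraction:
            if not 0.0 <= a.strength <= 1.0:
                raise ConfigError("attraction strength must be in [0, 1]")
            if a.condition not in self.conditions:
                raise ConfigError(f"attraction condition '{a.condition}' unknown")

    @property
    def phenotypes(self) -> list[str]:
        names: list[str] = []
        for d in self.domains:
            for p in d.composition:
                if p not in names:
                    names.append(p)
        return names

    @property
    def marker_names(self) -> list[str]:
        first = next(iter(self.marker_model.values()))
        return list(first)


@dataclass
class SyntheticTruth:
    """Planted labels aligned 1:1 with the generated cell table."""

    df: pd.DataFrame  # roi_id, cell_id, domain, phenotype
    attraction: list[Attraction]
    config: SyntheticConfig

    def check_aligned(self, table: CellTable) -> None:
        if len(self.df) != len(table.df) or not (
            (self.df["roi_id"].to_numpy() == table.df["roi_id"].to_numpy()).all()
            and (self.df["cell_id"].to_numpy() == table.df["cell_id"].to_numpy()).all()
        ):
            raise IntegrityError("truth and table are not aligned row-for-row")

    def with_true_phenotypes(self, table: CellTable) -> CellTable:
        """Copy the planted phenotype labels into a table (oracle labelling)."""
        self.check_aligned(table)
        return table.with_column("phenotype", self.df["phenotype"].to_numpy())


def _assign_domains(xy: np.ndarray, config: SyntheticConfig, rng) -> np.ndarray:
    w, _ = config.roi_size
    k = len(config.domains)
    if config.spatial_layout == "blocks":
        idx = np.minimum((xy[:, 0] / (w / k)).astype(int), k - 1)
    else:  # seeded Voronoi blobs, seeds assigned to domains round-robin
        n_seeds = k * config.blob_seeds_per_domain
        seeds = rng.uniform([0, 0], config.roi_size, size=(n_seeds, 2))
        owner = np.arange(n_seeds) % k
        d2 = ((xy[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        idx = owner[np.argmin(d2, axis=1)]
    return idx


def _apply_attraction(
    xy: np.ndarray, pheno: np.ndarray, domain_idx: np.ndarray,
    entry: Attraction, radius: float, roi_size, rng,
) -> None:
    b_all = np.flatnonzero(pheno == entry.type_b)
    if entry.strength <= 0 or not len(b_all):
        return
    n_move = int(np.floor(entry.strength * len(b_all)))
    if n_move == 0:
        return
    movers = rng.choice(b_all, size=n_move, replace=False)
    for i in movers:
        anchors = np.flatnonzero(
            (pheno == entry.type_a) & (domain_idx == domain_idx[i])
        )
        anchors = anchors[anchors != i]
        if not len(anchors):
            continue
        a = anchors[rng.integers(len(anchors))]
        r = radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        xy[i] = xy[a] + [r * np.cos(th), r * np.sin(th)]
        xy[i, 0] = np.clip(xy[i, 0], 0, roi_size[0])
        xy[i, 1] = np.clip(xy[i, 1], 0, roi_size[1])


def generate_tissue(config: SyntheticConfig) -> tuple[CellTable, SyntheticTruth]:
    """Generate one multi-sample, multi-ROI tissue with ground truth.

    The returned :class:`CellTable` has markers and metadata but empty
    ``phenotype``/``cn`` columns — it is raw pipeline input. The planted
    phenotype and domain labels live in :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(config.seed)
    area = config.roi_size[0] * config.roi_size[1]
    phenos = config.phenotypes
    comp_matrix = np.zeros((len(config.domains), len(phenos)))
    for di, d in enumerate(config.domains):
        for pi, p in enumerate(phenos):
            comp_matrix[di, pi] = d.composition.get(p, 0.0)

    marker_names = config.marker_names
    mu = {
        p: np.array([config.marker_model[p][m] for m in marker_names])
        for p in phenos
        if p in config.marker_model
    }
    for p in phenos:
        if p not in mu:
            raise ConfigError(f"marker_model lacks phenotype '{p}'")

    rows, truth_rows = [], []
    for cond in config.conditions:
        active = [a for a in config.attraction if a.condition == cond]
        for s in range(config.samples_per_condition):
            sample_id = f"{cond}_m{s + 1}"
            for r in range(config.rois_per_sample):
                roi_id = f"{sample_id}_roi{r + 1}"
                n = rng.poisson(config.cell_density * area)
                n = max(n, 10)
                xy = rng.uniform([0, 0], config.roi_size, size=(n, 2))
                domain_idx = _assign_domains(xy, config, rng)
                pheno = np.empty(n, dtype=object)
                for di in range(len(config.domains)):
                    sel = domain_idx == di
                    pheno[sel] = rng.choice(
                        phenos, size=int(sel.sum()), p=comp_matrix[di]
                    )
                for entry in active:
                    _apply_attraction(
                        xy, pheno, domain_idx, entry,
                        config.attraction_radius, config.roi_size, rng,
                    )
                markers = np.exp(
                    np.stack([mu[p] for p in pheno])
                    + config.marker_sigma * rng.standard_normal((n, len(marker_names)))
                )
                for i in range(n):
                    rows.append(
                        (f"c{i + 1}", roi_id, sample_id, cond, "unclassified",
                         xy[i, 0], xy[i, 1], None, None, *markers[i])
                    )
                    truth_rows.append(
                        (roi_id, f"c{i + 1}",
                         config.domains[domain_idx[i]].name, pheno[i])
                    )
    df = pd.DataFrame(rows, columns=list(STANDARD_COLUMNS) + marker_names)
    table = CellTable(df, marker_names)
    truth = SyntheticTruth(
        df=pd.DataFrame(truth_rows, columns=["roi_id", "cell_id", "domain", "phenotype"]),
        attraction=list(config.attraction),
        config=config,
    )
    return table, truth


def truth_report(
    truth: SyntheticTruth,
    table: CellTable,
    comparisons: pd.DataFrame | None = None,
    reference: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Recovery metrics of a pipeline run against the planted truth.

    Returns adjusted Rand indices for phenotype and CN/domain recovery
    (domain ARI is ``None`` when only one domain was planted) and, when
    a comparison table and reference condition are supplied, a
    planted-vs-detected confusion table over phenotype pairs.
    """
    truth.check_aligned(table)
    report: dict = {}
    if table.df["phenotype"].isna().any():
        raise StateError("pipeline has not assigned phenotype labels")
    report["ari_phenotype"] = float(
        adjusted_rand_score(truth.df["phenotype"], table.df["phenotype"])
    )
    if truth.df["domain"].nunique() < 2:
        report["ari_domain"] = None
    else:
        if table.df["cn"].isna().any():
            raise StateError("pipeline has not assigned CN labels")
        report["ari_domain"] = float(
            adjusted_rand_score(truth.df["domain"], table.df["cn"])
        )
    if comparisons is not None and reference is not None:
        planted = {
            tuple(sorted((a.type_a, a.type_b)))
            for a in truth.attraction
            if a.strength > 0
        }
        ref = comparisons[
            (comparisons["group_a"] == reference)
            | (comparisons["group_b"] == reference)
        ]
        detected = {
            tuple(sorted(p))
            for p in ref.loc[ref["significant"], ["type_a", "type_b"]].itertuples(
                index=False, name=None
            )
        }
        all_pairs = sorted(
            {tuple(sorted(p)) for p in ref[["type_a", "type_b"]].itertuples(
                index=False, name=None)}
            | planted
        )
        report["attraction_confusion"] = pd.DataFrame(
            {
                "type_a": [p[0] for p in all_pairs],
                "type_b": [p[1] for p in all_pairs],
                "planted": [p in planted for p in all_pairs],
                "detected": [p in detected for p in all_pairs],
            }
        )
    return report


def config_to_dict(config: SyntheticConfig) -> dict:
    """Plain-dict echo of a config (for YAML manifests)."""
    d = asdict(config)
    d["roi_size"] = list(config.roi_size)
    d["conditions"] = list(config.conditions)
    return d
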