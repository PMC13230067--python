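# Methods

## Scope and data model

`cnx` analyzes segmented multiplexed-imaging data at the per-cell level.
The unit of input is a cell table: one row per cell with an ROI id, a
sample id (mouse or patient), a condition label, centroid coordinates in
micrometres, and a nonnegative intensity per marker. ROIs are disjoint
image fields; all spatial computation is strictly per-ROI. Samples map
to exactly one condition; the ROI is the default unit of statistical
replication (see *Decision rule*). Coordinates are assumed to be µm; a
`pixel_size_um` schema entry rescales pixel data at read time, because
the 20 µm graph-pruning threshold is only meaningful in physical units.
Negative intensities (a by-product of spillover compensation) are
clamped to zero with a warning.

## Phenotyping

Markers are transformed with the inverse hyperbolic sine,
`asinh(x / c)` with cofactor `c = 5` (configurable), the standard
variance-stabilizing choice for ion-count cytometry intensities; each
marker is then clipped at its 99.9th percentile to tame hot pixels and
min–max scaled to [0, 1]. The transform is monotone per marker below
the clipping point; constant columns map to zero.

Clustering follows the Phenograph family: a k-nearest-neighbor graph in
marker space (Euclidean, k = 50 by default), each candidate edge
weighted by the Jaccard overlap of the two endpoints' k-neighbor sets,
then Louvain modularity maximization. Louvain's vertex-order randomness
is fixed by seeding, so the partition is deterministic given (data, k,
seed). Cluster → cell-type mapping is deliberately manual (an expert
reads the cluster × marker z-score matrix); unmapped clusters are
labeled `undefined`. The z-score matrix standardizes per-cluster mean
expression across clusters (ddof = 1), flagging constant markers
instead of dividing by zero.

Modularity clustering over-partitions at scale: on tissues of a few
thousand cells it can split one large, internally homogeneous cell type
into two pure sub-clusters (real studies observe 20+ clusters for ~15
annotated types and merge them during curation). The validation
benchmark therefore measures recovery on ~400-cell tissues, where the
blob structure and the k = 50 neighborhood size are commensurate, and
reports the mean adjusted Rand index over 20 seeds.

## Interaction graph

Candidate cell–cell contacts are the edges of the per-ROI Delaunay
triangulation of cell centroids, pruned at `max_dist = 20` µm — about
two cell diameters, so surviving edges connect cells that plausibly
touch. Exactly coincident centroids are separated by a deterministic,
seeded jitter of 1e-6 µm before triangulation (reported in the run
manifest); edge lengths are computed from the original coordinates.
Fewer than three distinct or fully collinear points cannot be
triangulated and either raise an error or (in batch mode) yield an
edgeless ROI whose cells remain in the analysis as isolated. Cells
whose incident edges are all pruned likewise stay, with degree 0.

The implementation (scipy/Qhull) is validated against a brute-force
O(n⁴) oracle that tests the empty-circumcircle property over all point
triples; the two agree exactly on random point sets, which are in
general position almost surely. Exactly cocircular configurations (e.g.
perfect grids) admit multiple valid triangulations; there the oracle
comparison is made meaningful by a symmetry-breaking jitter.

## Cellular neighborhoods

Each cell's microenvironment is the normalized phenotype histogram of
its 1-hop graph window — the cell itself plus its pruned-Delaunay
neighbors. Including the index cell guarantees a well-defined window for
isolated cells (a one-hot vector). Windows average ~7 cells, the
intrinsic scale of a planar Delaunay 1-hop neighborhood; this is the
resolution limit of CN detection.

Composition rows from all ROIs, samples and conditions are clustered
jointly with k-means (k-means++, 10 restarts, best inertia), so CN
identities are directly comparable across conditions — the premise of
any "CN composition is stable over time" statement. `n_cn` defaults
to 6. Fitted clusters are renamed CN1…CNk by descending size (ties
broken by original cluster index) for stable reporting; empty clusters
trigger a reseeded refit (≤ 5 attempts) before being accepted with a
warning. Model selection for `n_cn` is out of scope.

## Interaction statistic and decision rule

For each ROI r, CN c and unordered phenotype pair (A, B), the statistic
is

    normalized(r, c, A, B) = n_edges / n_cells × 100,

where `n_edges` counts pruned-Delaunay edges whose *both* endpoints lie
in CN c of ROI r and whose endpoint phenotypes are {A, B} (each
undirected edge counted once; A–A edges once per edge), and `n_cells`
is the number of cells of CN c in ROI r. Edges bridging two CNs are
excluded from all pairs and reported as a diagnostic count. Zero-count
pairs are materialized as explicit zeros, so a pair absent from an ROI
enters downstream comparisons as 0 rather than as missing data.

Group comparison treats each ROI's normalized value as one observation
(`unit="roi"`, matching the per-ROI normalization; `unit="sample"`
averages each sample's ROIs first, as a pseudoreplication-sensitivity
mode). Per (CN, pair): one-way fixed-effects ANOVA across conditions,
then all-pairs Tukey HSD. Tukey p-values are computed from the
Tukey–Kramer studentized-range statistic

    q_ij = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)),

evaluated against scipy's studentized-range distribution with k groups
and N − k degrees of freedom; the package's values agree with scipy's
independent `tukey_hsd` implementation to < 1e-6. A condition pair is
*significant* iff ANOVA p < 0.05 AND its Tukey p < 0.05. Zero
within-group variance is resolved explicitly (p = 1 for equal means,
p = 0 otherwise) and flagged `degenerate`; hypotheses lacking two
conditions with ≥ 2 observations are flagged `untestable` rather than
dropped. No correction is applied across (CN, pair) hypotheses by
default — the decision rule is exactly the dual ANOVA + Tukey rule —
but Benjamini–Hochberg adjustment of the ANOVA p-values is available
(`p_adjust="bh"`). Reports are filtered to significant rows involving a
declared reference condition, optionally restricted to pairs touching a
declared immune-type set (a display convention, not an inference step).

## Synthetic tissues

The generator emulates the statistical structure of a multi-condition
IMC study: conditions × samples × ROIs (defaults 3 × 3 × 3), ROI
rectangles partitioned into spatially contiguous domains — parallel
strips or seeded-Voronoi blobs — each with its own phenotype
composition. Cells arrive as a homogeneous Poisson process (default
0.008 cells/µm², a realistic segmented-cell density; ~1,300 cells per
default 400 × 400 µm ROI), phenotypes i.i.d. from the domain
composition, markers log-normal per phenotype (one bright canonical
marker each, σ = 0.35 on the log scale). The default domains are crisp
gut-like compartments — epithelium (85 % epithelial, 10 % CD8 T), an
immune-rich lamina propria, a muscularis of smooth muscle and vessels —
with pairwise composition L1 distances of 1.5–1.9.

Attraction between phenotypes A and B in a chosen condition is planted
by relocation: a fraction θ ∈ [0, 1] of B cells is moved to a uniform
point within a 10 µm disc around a uniformly chosen same-domain A cell.
θ = 0 reproduces the null process exactly; the expected A–B edge count
is monotone in θ. Relocation adds roughly 0.5–1 extra A–B Delaunay edge
per moved cell, so large relative effects require a low baseline: the
power benchmark uses A and B at 8 % each in one domain at density
0.004 cells/µm², where θ = 0.8 raises the expected normalized statistic
~3.3-fold.

What the generator does *not* emulate: segmentation errors, marker
spillover, spatial gradients within a domain, cell-size variation,
irregular tissue boundaries, or between-sample batch effects in marker
space (between-sample variability enters only through Poisson and
composition sampling). Passing benchmarks therefore demonstrate
algorithmic correctness and statistical calibration under the stated
model, not robustness to acquisition artefacts.

## Validation battery and problem sizes

`cnx.validation` (exercised by the test suite and by
`scripts/acceptance.py`) uses desk-scale problem sizes chosen so the
whole battery runs in minutes on one CPU while each check retains its
meaning: 100 random point sets of n ≤ 50 for the Delaunay oracle (the
O(n⁴) oracle is the binding constraint); ~400-cell tissues × 20 seeds
for phenotype recovery; 250 µm-wide domain strips (ROI 750 × 300 µm)
× 20 seeds for CN recovery, where the adjusted Rand index is limited by
the ~10 % of cells whose windows straddle a domain boundary; 500 null
datasets (3 conditions × 3 ROIs, ~2,700 cells each) for type-I-error
calibration, tracking both the flagged fraction of (CN, pair)
hypotheses and the uniformity of a reference hypothesis's ANOVA
p-values; 100 replicates of the planted-attraction design (27 ROIs,
~650 cells each) for power. Phenotypes are taken from the planted truth
in the CN/interaction benchmarks so each stage is tested in isolation;
the full chain including clustering is exercised by the pipeline
determinism check and the worked examples.

## Reproducibility

Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds deterministically from one global seed and echoes all
parameters, seeds, versions and row counts into a YAML manifest.
Rerunning a pipeline config reproduces byte-identical artifacts.

## Known limitations

- The Delaunay graph predicts contact from centroid geometry only;
  membrane contact is not verified, and the 20 µm threshold is a
  convention whose unit-correctness depends on accurate pixel size.
- ROI-level replication ignores within-sample correlation of ROIs
  (pseudoreplication); the sample-level mode exists precisely to gauge
  that sensitivity, and mixed models are out of scope.
- The normalized statistic divides edge counts by CN cell count, not by
  pair-specific abundance, so it shifts when phenotype *frequencies*
  change even if contact *preferences* do not; permutation-null
  frameworks address that question and are deliberately not the
  inference path here.
- k-means CN detection assumes roughly spherical composition clusters
  and a known `n_cn`; boundary cells are intrinsically ambiguous at the
  1-hop window scale.
- With many (CN, pair) hypotheses and no cross-hypothesis correction,
  the expected number of false positives grows with the number of
  phenotypes; the BH option exists for users who want control.
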