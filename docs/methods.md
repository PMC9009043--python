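# Methods

This note records the models, numerical choices and limitations behind
`imcscope`, stage by stage.

## Synthetic tissue model

The simulator is the package's ground-truth source and defines the study
conditions the tests run under.

**Geometry.** Cells are disks with radius ~ N(r, 10% of r), clipped at
2 px, placed by rejection sampling with a ≥ 1 px gap between disks so the
true label mask is an unambiguous segmentation oracle. Defaults: immune
cells r = 3 px, macrophages 4 px, hepatocytes 5 px at 1 µm/px — liver
parenchyma has unusually uniform cell morphology, which is what makes it a
favorable tissue for watershed segmentation. The desk-scale ROI is
300 × 300 px; 1000 × 1000 px (a full 1 mm² ablation) runs through the same
code path via `roi_shape_px`.

**Spatial structure.** NR ROIs draw immune cells from a homogeneous point
process (sparse, isolated infiltrate; ~40 immune vs ~220 hepatocytes). CR
ROIs concentrate ~200 immune cells in 4 Gaussian aggregates (SD 18 px) over
~180 hepatocytes; when aggregates saturate, the proposal SD inflates
gradually rather than failing. A planted pair (A, B, p) places a fraction p
of B cells at a 1–2 px boundary gap from a randomly chosen A cell (well
inside the 4 px adjacency radius); anchor-phenotype cells are placed first
so planted partners always find room. The default CR attraction is
(Macrophage-2, CTL-2, 0.8), mirroring the strongest macrophage–cytotoxic
T-cell contacts reported in rejecting grafts. An unplaceable configuration
raises an error naming the attempted disk density.

**Expression and noise.** Each cell draws a per-marker mean from a
mean-preserving lognormal (CV 0.2) around its phenotype profile, rendered
as a constant Poisson rate over the cell disk on top of a uniform
background rate (0.2 counts). A pure-Poisson mode exists for debugging.
The 12 bundled profiles (11 immune + hepatocyte) encode the marker logic of
the panel: B-cells CD20⁺; two CTL populations CD45/CD3/CD8 at bright vs dim
levels; two CD68⁺ macrophage populations with **zero CD3**; two
unspecified CD45/CD3 T-cell populations; CD45RA⁺ naïve T-cells; CD66a⁺
neutrophils; HLA-DR⁺ cells; CD45-only "other leukocytes"; hepatocytes are
zero on all immune markers. The bright/dim "-1"/"-2" pairs exist because
graph clustering in real IMC data separates lineages by signal level, not
only by marker identity. No published per-phenotype abundance table exists,
so the default NR/CR mixes were chosen once to match the qualitative
orderings (neutrophils and other leukocytes relatively enriched in NR;
Macrophage-2 absent from NR and, with CTL-2 and the other T-cell
populations, enriched in CR).

**Nuclear channel.** The iridium channel renders 85% of its mean inside a
nucleus disk (0.55 × cell radius) and 15% over the whole cell — residual
cytoplasmic intercalation — so that nuclear, cytoplasmic and background
pixel classes are all distinguishable even on marker-null hepatocytes.
Collagen is a smooth banded field (random orientation, 60–120 px
wavelength, low-frequency amplitude modulation) independent of cell
positions: a structural channel that must not influence immune identity.

**Cohort feature simulator.** For the modeling stage a feature-level
generator draws per-ROI median-marker vectors directly: marker-role
baselines, a shared per-ROI "infiltrate load" factor (lognormal, CV 0.3)
multiplying all immune markers, per-marker lognormal noise (CV 0.3), and a
×2.2 CR shift on immune markers. The shared load factor makes immune
markers co-vary across ROIs, so PC1 draws balanced contributions from all
of them (~50% of variance) — the structure seen in the real cohort — while
the shift magnitude reflects a rejecting graft whose immune infiltrate is
an order of magnitude larger than baseline. Image-derived per-ROI medians
over *all* cells would not carry this signal in the simulator because the
hepatocyte majority is immune-marker-null; the image pipeline's cohort
signal lives in the immune subpopulation counts instead, and the full
pipeline uses those by default (`model.features: clusters`).

**What the simulator does not model:** channel spillover between metal
tags, ablation artifacts, tissue autofluorescence, 3D structure, irregular
cell shapes, or patient-level correlation between ROIs. Passing tests
therefore demonstrate that the algorithms recover planted structure under
idealized noise, not that they are robust to every artifact of real
acquisitions.

## Segmentation

Hot pixels: a pixel whose value exceeds 5× the median of its 3 × 3
neighborhood is replaced by that median (factor configurable). On
low-background IMC images this also zeroes isolated single-count background
events, which is intended. Intensities are then bilinearly upscaled 2×; all
structural parameters below are in 2×-grid pixels.

The 3-class pixel classifier is a seeded random forest (60 trees, leaf
size 2) over per-channel features: Gaussian smoothings at σ ∈ {1, 2, 4},
gradient magnitude, and Laplacian (5 features × 10 channels). It trains
from sparse label images — on synthetic data these are sampled from ground
truth (1500 px/class by default), standing in for interactive brush
labeling with the same 3-class contract.

Nuclei are connected components of (nuclear probability ≥ 0.5), split by
watershed on the Euclidean distance transform. The distance map is smoothed
(Gaussian σ = 1) before peak finding: near-circular nuclei otherwise
produce plateau double-peaks and spurious splits. Seeds must be ≥ 3 px
apart; nuclei under 4 px² are dropped. Cells grow from nuclei by a second
watershed on distance-to-nucleus, limited to 5 px of expansion and to
pixels where background probability < 0.5; watershed flooding guarantees
each cell stays connected and boundary pixels go to the nearer seed (ties
resolved deterministically by the flooding order). Masks return to 1× by
taking the top-left pixel of each 2 × 2 block, preserving label identity.

Per-cell measurement is the **mean** over the cell's 1× pixels of the
hot-pixel-filtered, otherwise untransformed counts; cluster profiles later
use the **median** over cells. Both statistics appear in the field's
pipelines and are easy to conflate, so the choice is fixed here once.

Neighbor graph: cells are adjacent when dilating one cell's pixels by a
Euclidean disk of radius 4 px (= 4 µm) reaches the other — equivalently,
minimum pixel-to-pixel distance ≤ 4 — computed on boundary pixels with a
KD-tree and verified against brute-force pairwise distances in tests.

## Phenotyping

Clustering follows the Phenograph recipe on raw (untransformed) per-cell
mean intensities: exact kNN (k = 75), edges reweighted by the Jaccard
overlap of neighbor sets (zero-overlap edges dropped), Louvain modularity
maximization with a fixed seed, cluster ids ordered by decreasing size. A
property worth knowing: when k is much smaller than a cluster's true size,
modularity maximization refines large uniform clusters into pure
sub-communities; exact recovery of planted partitions holds when k is a
sizeable fraction of the cluster size (the k = 75 default against the
≥ 300-cell phenotypes used in tests). tSNE is Barnes-Hut (perplexity 30,
θ = 0.5, seeded), with perplexity lowered and logged when n ≤ 3 ×
perplexity; the historical "initial dimensions 110" PCA cap is inert for a
10-marker panel and kept only as provenance.

Cluster profiles are cluster × marker medians with column z-scores
(population SD, ddof 0 — used for every z-score in the package; zero-SD
columns give z = 0). A cluster is called immune when some immune-role
marker both stands out relatively (z ≥ 1.0) and carries real signal
(median ≥ 1 count); the absolute floor exists because column
standardization of two noise clusters yields z = ±1 mechanically. The
published analyses state the immune criterion only qualitatively
("associated with at least one immune marker"), so this rule is a declared,
configurable substitute. Phenotype labels follow a positivity decision
chain (CD20 → B-cell; CD68 → Macrophage; CD3∧CD8 → CTL; CD3 → Other
T-cell; CD45RA → Naïve T-cell; CD66a → Neutrophil; HLA-DR → HLADR+; CD45 →
Other Leukocyte), where a marker is positive when its cluster median
reaches 50% of the column's maximum median — a relative rule, because the
dim "-2" variants of a lineage are positive for their defining markers
without reaching z ≥ 1 once several clusters share the marker. Clusters
sharing a pattern are numbered -1, -2, … by decreasing size; the numbering
is a size convention, so a dim variant may receive -1 if it is the larger
cluster.

## Quantification

Median marker signal per ROI is taken over **all** cells. Immune
subpopulation proportions divide by the ROI's immune-cell total; an ROI
with zero immune cells yields missing values, not zeros. Count matrices are
z-scored within subpopulation across ROIs (population SD). Cohort
differences use the two-sided Wilcoxon rank-sum test: exact null when both
groups have n ≤ 10 and no ties, tie-corrected normal approximation
otherwise; identical pooled values report p = 1. Raw p is the headline
number (matching the published convention) with Benjamini–Hochberg q
reported alongside. ROIs are treated as independent observations; a
`collapse_by_patient` helper averages ROIs within patient for designs where
that assumption is in doubt. Two immune percentages with different
denominators are computed and named explicitly — a cohort's share of all
immune cells, and the immune fraction within a cohort's own cells — because
the two are easy to conflate (91.1% and 16.6% in the motivating cohort are
one of each).

## Neighborhood analysis

The pair statistic for ordered (A, B) is the mean count of B-neighbors per
A-cell (A = B allowed; a cell is not its own neighbor). The null permutes
phenotype labels uniformly over cells with the graph fixed; two scopes are
exposed — all cells (the 29-cluster-style run) or immune cells only (the
immune-focused run) — since published descriptions of the cited packages
document all-cell permutation but the immune-only analysis conditions on
the non-immune scaffold. p-values use the +1 pseudo-count estimator,
p = (1 + #{perm ≥ obs}) / (n_perm + 1), which can never return 0 and is
never anti-conservative. All pairs within an ROI share one matched
permutation stream, so a single pass of label shuffles prices every pair.
Verdicts: interaction if p_high < α, avoidance if p_low < α; since
p_high + p_low > 1, the two can never fire together at any α ≤ 0.5. No
multiple-testing correction is applied across pairs by default (thresholds
are per pair, as published); BH is available downstream.

Calibration is assessed per tail: a procedure that runs two one-tailed
tests at level α flags either verdict at up to 2α under a continuous null,
so the meaningful checks are that the interaction tail rejects at ≈ α
where the null statistic is near-continuous (dense graphs, few phenotypes),
that the avoidance tail never exceeds α (it is conservative on sparse
graphs because the count statistic is floored at zero), and that the
either-verdict rate stays below 2α. The acceptance suite measures all
three on 200 label-randomized dense ROIs and checks Monte-Carlo p-values
against exhaustive enumeration on 7-cell graphs.

Cohort aggregation: per pair, 100 × (#interaction ROIs − #avoidance ROIs) /
#testable ROIs, so one interaction and one avoidance cancel; pairs testable
in no ROI are missing.

## Modeling

PCA centers columns and by default scales them to unit variance
(population SD), because heavy-metal tags differ widely in raw signal
yield and unscaled PCA would be dominated by the brightest markers; an
unscaled mode exists. Decomposition is by SVD of the processed matrix with
a deterministic sign convention (largest-magnitude loading of each
component made positive), explained variance as percentages summing to
100, and the contribution of variable j to component k as
100 × loading²ⱼₖ / Σᵢ loading²ᵢₖ. Reconstruction with all components
reproduces the processed matrix to < 1e-8, which the tests assert.

PC1 is compared between cohorts with the same rank-sum engine as the
quantification stage, then fed to a univariate logistic regression of
chronic rejection. With 8-vs-24 designs and strong effects the cohorts
frequently separate completely along PC1, where the unpenalized MLE
diverges; separation is detected (non-convergence or a scaled slope beyond
30) and the model refits with a ridge penalty of 1.0 (intercept
unpenalized) and raises a flag. Reported per model: per-ROI P(CR), the
count of ROIs whose correct-class probability reaches 0.75, and outliers
(correct-class probability < 0.5).

The marker correlation network defaults to Spearman (the published choice
of coefficient is unstated; Pearson is a flag away), emitting edges with
|r| ≥ 0.8; constant columns are excluded and reported as missing.

## Pipeline and determinism

One master seed derives every stage seed through `SeedSequence`; identical
configs reproduce byte-identical tables, which the test suite asserts by
hashing outputs of two independent runs. Each stage writes a JSON manifest
(parameters, seed, SHA-256 of outputs). Config files are YAML with unknown
keys rejected and cross-field checks (α ∈ (0,1), radius > 0, k ≥ 1)
applied before any stage runs; defaults are k = 75, 4 px radius, 5000
permutations, α = 0.01.

## Problem sizes in tests

The suites run at desk scale, chosen as the smallest sizes at which each
statistical property is informative: 300 × 300 ROIs with ~380 cells for
segmentation; 8 ROIs × ~505 cells (≥ 300 per phenotype) for clustering
recovery; 200 × 999-permutation null ROIs for calibration; 15 + 15 ROIs ×
5000 permutations for planted-interaction power; 20 replicate 32-ROI
cohorts for modeling. Full-scale 1 mm² ROIs run through the same code by
changing `roi_shape_px` and cell counts.

## Known limitations

Segmentation assumes compact, roughly convex cells (liver-like tissue);
heavily elongated or overlapping cells would need a different boundary
model. The immune-annotation rules are specific to this 10-marker panel.
Louvain community structure, although seeded and deterministic here, can
change across networkx versions. The permutation test treats the ROI as
the exchangeability unit and ignores patient-level clustering, as does the
Wilcoxon stage.
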