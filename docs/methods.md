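# Methods

This note documents the models and procedures implemented in `renimap`, the
parameter choices that matter, the design decisions taken where the design
was genuinely open, and what the synthetic-tissue generator does and does not
emulate.

## Image preparation

Each marker channel is corrected with its blank-cycle counterpart:
`out = clip(channel − blank, 0) / sd(blank)`, elementwise.  The standard
deviation is the population (ddof = 0) sd of the blank image — a
deterministic quantity of the image, not a sample estimate.  Negative
differences are clipped to zero before normalization because fluorescence is
non-negative.  Percentile normalization maps a channel to
`(x − min) / (P99 − min)` clipped to [0, 1], with percentiles by linear
interpolation between order statistics (numpy's default); a constant channel
maps to all zeros.  Correction and normalization are applied per slide, not
per tile; tile stitching and registration are upstream of this package.

## Cell bodies, MFI, compartments

Nuclear instance masks are expanded by a bounded Voronoi dilation: every
pixel within `radius_px` (default 7, ≈ 1.05 µm at the 0.1507 µm/px
acquisition scale) of a nucleus joins the nucleus whose **nearest pixel**
(not centroid) is closest; distance ties go to the lower label id.  The
implementation scans all integer offsets inside the radius and keeps the
lexicographic (distance², label) minimum per pixel, which is exact and
O(radius²) passes over the image.  Bodies therefore contain their nuclei and
are pairwise disjoint; tests verify equality with an exhaustive
nearest-nucleus oracle on small images.

MFI is the mean channel intensity over the body pixel mask.  Standardization
is a per-channel population z-score over whatever cell set is supplied;
pooling tables from all biopsies before standardizing (as the gating stage
expects) makes thresholds comparable across cohorts.

Peritubular and periglomerular rings are the binary dilation of the
structure by `round(ring_width_um / pixel_size)` pixels minus the structure.
The ring width is not a measured quantity; it defaults to 10 µm and is a
config parameter.  Because rings can overlap structures and each other, a
fixed priority resolves each pixel — glomerular > tubular > periglomerular >
peritubular > interstitial — chosen so that structures dominate their rings
and rings dominate the interstitium.  Cells are assigned by centroid lookup
in the resolved map, so the five compartments partition the tissue and every
cell gets exactly one compartment.

Tubule objects are dropped as false positives (red-blood-cell clusters,
interstitial lymphocyte aggregates) only when **all five** conditions hold on
the object's normalized marker means: µ(CD10) < 0.8, µ(MUC1) < 0.8,
µ(Claudin-1) < 1, µ(CD138) < 1, 0.25 < µ(MUC1)/µ(CD10) < 6.5.  The
conjunction reading follows the narrative of the rule (low tubule markers
*and* uniformly high staining); with µ(CD10) = 0 the ratio condition is
treated as unsatisfied and the object kept, with a log line.  The filter is
idempotent.

Instance-segmentation scoring matches predicted to reference objects
greedily by descending IoU, one-to-one, requiring IoU ≥ threshold
(default 0.25).  `average_precision` is TP/(TP+FP+FN), the common
cell-segmentation convention.  Two empty masks score 1 by convention.

## Annotation

Marker positivity thresholds come from multi-Otsu (between-class variance
maximization on a 256-bin histogram, delegated to scikit-image and checked
against an exhaustive search in the tests; cut positions inside empty
histogram gaps tie, so equivalence is asserted on achieved variance).  The
number of Otsu classes per marker defaults to 3 and is configurable
per marker; with k ≥ 3 the candidate that most closely matches manual spot
validation is selected: the largest candidate below all of the validated
positive MFIs, falling back to fewest violations (ties to the smaller
threshold).  Spot references should be *typical* positive cells; feeding the
extreme top of the positive distribution biases selection upward.

The gating tree is a strict binary tree over marker-positivity decisions,
shipped as JSON (`renimap/data/gating_tree.json`): 33 named leaf classes
over 26 cardinal markers, with `null` leaves for non-classified.  Validation
enforces that no path tests a marker twice and that named leaves are unique.
Gating operates on standardized MFI by default and records the full path per
cell as an audit trail.  Regulatory markers such as FOXP3 appear only inside
T-cell subtrees, never at the root.  Branch placements that published
supplementary material alone would pin down (the NK branch position, the
catch-all leaf, the ordering of structural markers) are listed as
placeholders inside the config.

## Cohort statistics

Densities are counts over compartment area in mm²; zero-area compartments
report missing, not zero.  Whole-biopsy proportions are taken over
classified cells only.  Cohort contrasts use the two-sided Mann–Whitney U
test — exact when both samples are ≤ 8 without ties, tie-corrected normal
approximation otherwise (scipy's rule, verified against full enumeration for
small n) — with Benjamini–Hochberg step-up per cohort pair over the family
of classes.  Log2 fold changes use a pseudocount ε = (smallest positive
density)/10 to keep zero densities finite.  Spearman correlation uses
average ranks; p-values come from the t-approximation for n ≥ 10 biopsies
and an exact pairing-permutation null (all n! pairings, evaluated
vectorized) for smaller n.  The significance mask of the correlation matrix
uses unadjusted p < 0.05; BH applies only to the cohort contrasts.  Damage
scores threshold the normalized MXA/Claudin-1/COLIII channels by Otsu unless
a threshold is supplied, and count a cell as inflamed-tubule when it is MXA⁺
and Claudin-1⁺ *and* inside the tubular compartment.

## Neighborhoods

DBSCAN uses standard semantics (core iff ≥ minPts neighbors within ε
including self; clusters are connected core points plus border points;
border points reachable from two clusters go to the first discovered, which
is deterministic under a fixed point ordering).  The literal "all points are
core points" reading is available as an `all_core` switch, under which
clusters become connected components of the ε-graph.  Defaults: ε = 85 px
(≈ 13 µm), minPts = 5, ≥ 20 members for phenotyping.

Neighborhood features are the per-class member proportions plus the raw
member count; the count column is z-scored immediately before clustering so
counts and proportions share a scale.  K is selected by bootstrap: for each
K, the mean over 3,000 (tests and the acceptance script use 200) draws of a
75 % subsample of the K-means within-cluster SSD; the chosen K is the knee —
the maximum positive second difference of the curve normalized to its first
value.  A knee is accepted only if the curve is nearly flat beyond it
(≤ 25 % of the total drop remains after the knee); a smooth featureless
decay — e.g. a single blob — fails that criterion and returns
`k_star = min(k_range)` with a low-confidence flag.  Full curves are
returned so the choice is auditable.  Phenotyping uses K-means with
distance-weighted (k-means++) seeding and 10 restarts, keeping the best SSD;
per cluster and feature the leave-one-out Z is
`(mean_in − mean_out) / sd_out` with the population sd outside the cluster,
missing where that sd is zero.

The inner loop of the bootstrap scan uses a compact Lloyd iteration written
in numpy (k-means++ seeding, identical objective); at tens of rows per
subsample it is an order of magnitude faster than constructing a full
estimator object per draw, which matters at thousands of (rep × K) fits.
Phenotyping and gene clustering use scikit-learn's KMeans.

## Trajectories

The six axes are total CD8⁺ T, total CD4⁺ T, CD163⁻ macrophages, CD163⁺
macrophages, and HLA-II⁺/⁻ inflammatory monocytes; a configurable class map
assigns gating-tree leaves to axes.  Axes below a density floor (default
5 cells/mm², chosen so near-zero axes cannot block predominance in
low-grade biopsies) are excluded from comparison; an axis is predominant iff
it exceeds `fold` (default 2) times every other above-floor axis.  Under
this all-axes rule at fold ≥ 1 at most one axis can be predominant; the
categorical summary therefore also detects dual co-dominance (two axes
within a fold of the top that jointly exceed fold times all others) and
otherwise labels multi-lineage; all axes below the floor is
low-inflammation.  A pairwise mode compares each axis only against its
lineage partner (CD163⁺/CD163⁻, HLA-II⁺/HLA-II⁻, CD8/CD4).  The predominant
set is invariant to rescaling all six densities (when no axis crosses the
floor) and shrinks monotonically in `fold`; both are property-tested.

## Transcript niches

Transcript coordinates (µm) are rasterized by `floor(µm / 10)` to a 10 µm
grid.  DBSCAN runs per anchoring gene with gene-specific ε (CD3E 40, CD14
20, FCGR3A 30 px; minPts 5).  Each cluster's footprint is built by stamping
radius-10 disks at member pixels, closing with a disk-5 footprint, filling
holes < 500 px, dropping objects < 100 px, Gaussian blur σ = 2, and
re-binarizing at 0.5 (a threshold must be fixed to relabel; 0.5 is the
natural choice after blurring a binary mask); connected components are then
relabelled.  Clusters eliminated by the morphology pass are logged — a
rule-based, auditable stand-in for interactive manual correction.

Masks from different anchor genes are kept separate rather than merged into
one label image: the same tissue niche is typically dense in several
anchors, and merging would overwrite and fragment overlapping footprints;
each (gene, label) row instead gets densities over its intact mask.
Per-niche gene density is transcript count inside the mask over mask area in
µm².  The HLAII composite is the sum of the five component HLA gene
densities.  Clustering uses the 14 immune features z-scored per column;
marker genes per cluster are the genes with one-sided (greater) rank-sum
p < 0.05 and positive mean difference, top 10 by p.

## Synthetic tissue

The generator is first-class, tested code; its defaults define the
conditions under which recovery is demonstrated.

* **Geometry.** Glomeruli are disks (radius 25–40 µm), tubules are capsules
  (width 12–20 µm, length 3–6 × width) with a hollow lumen, nuclei are
  disks; the simplest geometry that exercises the compartment logic.
  Structures are placed by rejection sampling; an impossible request raises
  a placement error naming the structure.
* **Cells.** Per-class counts are Poisson(abundance × area); positions are
  rejection-sampled so nucleus disks never overlap, keeping MFI ground
  truth exact.  Periglomerular enrichment multiplies the placement weight of
  enriched classes inside the periglomerular ring.  Compartment ground truth
  is assigned at placement with the same priority map the pipeline uses, so
  compartment recovery is exact by construction and the tests are
  well-posed.
* **Marker expression.** Cell MFI is `template_mean × exp(sd × N(0,1))` —
  multiplicative lognormal noise, default sd 0.25 with positive/negative
  template means 8/0.5, a separation at which gating recovers ≈ 98 % of
  labels.  Templates are derived from the gating tree itself
  (`templates_from_tree`), so zero-noise annotation is exact by
  construction.  The default panel includes rarer immune and renal
  parenchymal classes so that every tree marker has at least one positive
  class — otherwise its threshold would be unidentifiable, as in real
  tissue where structural cells dominate the table.
* **Rendering.**  Marker channels are a constant-plus-white-noise background
  field with each cell's MFI added over its Voronoi body; the blank channel
  shares the identical realized field, so blank correction recovers each
  cell's value exactly (scaled by 1/sd(blank)) at zero marker noise.  No
  PSF, spectral bleed-through, 3-D structure, FFPE artifacts, or stitching
  seams are modelled: passing recovery tests shows the analysis logic is
  correct, not that it is robust to those physics.
* **Cohorts.** Per-biopsy class densities follow a lognormal latent-factor
  model: `density = base × exp(Σ loading × z + ε)` with z ~ N(0,1) per
  factor and ε ~ N(0, 0.3).  Classes sharing a factor with loading 1 form
  planted covariant blocks (T cells; CD163⁺ macrophages; CD163⁻ macrophages;
  inflammatory monocytes; humoral cells).  Default cohort bases emulate a
  myeloid-heavy, CD163⁺-enriched disease (LuN-like), a T-cell-heavy disease
  (RAR-like) and a low-infiltrate normal control, at 700–900 total immune
  cells/mm² for the disease cohorts.
* **Niches.** Each niche type has a composition (proportions summing to 1),
  a radius, and a Poisson cell intensity; members are placed uniformly in
  the niche disk.  The canonical niche-recovery configuration
  (`niche_recovery_spec`) uses 90 %-dominant compositions and two intensity
  tiers (60 and 240 cells) with radius ∝ √intensity: because the count
  feature is z-scored to unit variance, a count column carrying no signal
  would dominate the within-cluster variance and erase the SSD knee, while
  a *linear* intensity gradient turns the planted clusters into a line with
  no knee either.  Two well-separated tiers give the count feature blob
  structure consistent with the planted phenotypes, as real neighborhood
  data shows (cluster sizes differ by integer factors), and the knee then
  identifies G for G ∈ {3..8} in ≥ 90 % of seeded runs.
* **Transcripts.** Per niche and gene, counts are Poisson with the niche
  type's rate (interpreted per niche) and positions uniform in the niche
  disk.  The transcript-scale layout (`transcript_niche_spec`) spaces niches
  ≥ 450 µm apart — beyond the largest anchor ε (400 µm on the raster) — so
  per-gene clustering cannot bridge distinct niches.

Problem sizes in the tests and the acceptance script (≈ 1–4 mm² fields at a
1 µm coordinate grid, 200 bootstrap repetitions, 20 recovery runs, 25-biopsy
cohorts) are chosen so the full suite completes in about a minute on one CPU
while keeping every statistical margin analytic (3σ Poisson bands, exact
enumeration for small-sample tests).

## Known limitations

* The shipped gating schema reproduces the published class *names* and
  hierarchy logic, but subtree placements marked as placeholders are this
  package's own choices.
* The knee criterion for K selection is a heuristic; the full SSD and delta
  curves are always returned so a user can override `k_star`.
* Compartment assignment is by centroid, so a cell body straddling a
  boundary is attributed wholly to one compartment.
* The damage-score stage assumes the MXA/Claudin-1/COLIII channels are on
  the normalized [0, 1] scale; Otsu thresholds on other scales should be
  overridden explicitly.
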