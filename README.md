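# renimap

Quantitative mapping of in-situ renal inflammation from multiplexed tissue
imaging.

Kidney biopsies from inflammatory diseases such as lupus nephritis or
allograft rejection carry dozens of immune cell populations whose identities,
densities and spatial arrangement differ between patients.  Cyclic
immunofluorescence imaging (CODEX-style) produces dozens of aligned marker
channels per section; `renimap` turns those channels — together with instance
masks for nuclei, tubules and glomeruli produced by upstream segmentation
tools — into annotated single-cell tables and the statistics that describe a
biopsy's inflammatory state.  It is written for computational pathology and
spatial-immunology groups who want each stage of such an analysis as a tested,
scriptable library function.

## What the pipeline computes

1. **Image preparation** — blank-cycle background subtraction
   (`out = clip(channel − blank, 0) / sd(blank)`) and per-channel min–max
   normalization to the 99th percentile.
2. **Cell bodies and MFI** — bounded Voronoi dilation of nuclear masks
   (default 7 px ≈ 1.05 µm at 0.1507 µm/px), per-cell mean fluorescence
   intensity (MFI) over the body mask, and population z-scoring across the
   pooled cell set.
3. **Annotation** — hierarchical gating: multi-Otsu thresholds per marker
   (between-class variance maximization on a 256-bin histogram), candidate
   selection against manually spot-validated positive cells, and a
   flow-cytometry-style decision tree.  The shipped schema declares 33 leaf
   cell classes over 26 cardinal markers.
4. **Compartments** — peritubular and periglomerular rings by binary
   dilation; the five compartments (glomerular > tubular > periglomerular >
   peritubular > interstitial, resolved in that priority) partition the
   tissue.  Tubule false positives are removed when all of
   µ(CD10) < 0.8, µ(MUC1) < 0.8, µ(Claudin-1) < 1, µ(CD138) < 1 and
   0.25 < µ(MUC1)/µ(CD10) < 6.5 hold.
5. **Cohort statistics** — class × compartment densities (cells/mm²),
   two-sided Mann–Whitney U contrasts with Benjamini–Hochberg control,
   Spearman covariance blocks, four scalar damage measures, and OLS
   correlates.
6. **Neighborhoods** — DBSCAN (ε = 85 px ≈ 13 µm, minPts = 5) over immune
   cell positions; neighborhoods with ≥ 20 members are phenotyped by K-means
   on class-proportion + total-count features, with K chosen as the knee of a
   bootstrap (75 % subsample) mean within-cluster SSD curve and per-cluster
   leave-one-out Z matrices for interpretation.
7. **Trajectories** — six-axis principal profiles (CD8 T, CD4 T, CD163⁻ and
   CD163⁺ macrophages, HLA-II⁺/⁻ inflammatory monocytes, cells/mm²) and a
   rule-based classification: an axis is predominant when it exceeds twice
   every other axis above a density floor.
8. **Transcript niches** — MERSCOPE-style transcript tables rasterized to a
   10 µm grid, per-gene DBSCAN around anchoring immune genes (CD3E ε = 40,
   CD14 ε = 20, FCGR3A ε = 30 px), fixed morphology post-processing into
   labelled niche masks, per-niche gene densities (transcripts/µm²), K-means
   over 14 z-scored immune genes (HLAII as a five-gene composite), and
   one-sided rank-sum marker-gene ranking.

A synthetic-tissue generator (`renimap.synthetic`) plants all of the
structure this analysis assumes — compartment geometry, class-specific marker
expression, covariant abundance blocks, spatial niches, periglomerular
enrichment, transcript point patterns — so that every stage has a recoverable
ground truth.

## Worked example

```python
import renimap.synthetic as rs
from renimap.segmentation import standardize_mfi
from renimap.gating import load_default_tree, compute_threshold_set, gate_cells
from renimap.compartments import build_compartment_masks, assign_compartment
from renimap.stats import compute_density_table
from renimap.trajectories import profile_from_densities, classify_trajectory

spec = rs.default_spec(image_shape=(1400, 1400), pixel_size=1.0, niche_specs=())
nuclei, tubules, glomeruli, cells, truth = rs.generate_biopsy(spec, seed=5)

tree = load_default_tree()
z = standardize_mfi(cells)
thresholds = compute_threshold_set(z, tree.markers(), k_classes=2)
gated = gate_cells(z, tree, thresholds)
print(f"annotation accuracy: {(gated['class_label'] == cells['true_class']).mean():.1%}")

comps = build_compartment_masks(tubules, glomeruli, ring_width_um=10,
                                pixel_size=spec.pixel_size)
gated = assign_compartment(gated.drop(columns=["compartment"]), comps)
table = compute_density_table(gated, comps)
profile = profile_from_densities(table["total"])
print(profile.round(1))
print(classify_trajectory(profile, fold=2, floor=5).summary)
```

prints

```
annotation accuracy: 98.4%
CD8 T                            54.6
CD4 T                            73.5
CD163- macrophage               125.5
CD163+ macrophage               131.6
HLAII+ inflammatory monocyte     39.3
HLAII- inflammatory monocyte     43.9
multi-lineage
```

The 2,162 generated cells on this 1.96 mm² field are re-annotated from their
(noisy) marker intensities at 98.4 % agreement with the planted labels; the
six-axis density profile shows a biopsy with co-dominant CD163⁺ and CD163⁻
macrophage axes plus substantial T-cell densities, hence no single
predominant trajectory.

A `renimap` command-line tool wraps the same stages (`simulate`, `prep`,
`segment-post`, `compartments`, `seg-eval`, `annotate`, `niches`,
`trajectories`, `transcripts`); run `renimap --help`.

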