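# imcscope

Single-cell analysis of Imaging Mass Cytometry (IMC) tissue images, built
around the immune microenvironment of chronic liver-allograft rejection.

IMC ablates a stained tissue section pixel by pixel (~1 µm spots) and reads
heavy-metal-tagged antibodies by mass spectrometry, giving one intensity
channel per marker. `imcscope` turns such multi-channel region-of-interest
(ROI) stacks into biology:

1. **Segmentation** — hot-pixel removal, 2× upscaling, a 3-class pixel
   classifier (nuclear / cytoplasm-membrane / background), watershed nuclei
   splitting, bounded cell expansion, and per-cell intensity measurement at
   1× on raw counts.
2. **Phenotyping** — Phenograph-style meta-clustering (exact kNN graph,
   k = 75, Jaccard edge reweighting, seeded Louvain), Barnes-Hut tSNE, a
   column-standardized cluster × marker median heatmap, and rule-based
   immune annotation (CD20 → B-cell, CD68 → Macrophage, CD3+CD8 → CTL, …);
   everything else collapses to "not immune cell".
3. **Quantification** — per-ROI median marker signal, immune subpopulation
   counts/proportions (immune-cell denominator), within-subpopulation
   z-scores, and Wilcoxon rank-sum cohort comparisons with BH q-values.
4. **Neighborhood analysis** — for each ordered phenotype pair (A, B), the
   mean number of B-neighbors per A-cell on a 4-pixel-radius mask-adjacency
   graph, tested against label permutations with two one-tailed Monte-Carlo
   p-values (`p_high` → interaction, `p_low` → avoidance); signed cohort
   aggregation where one interaction and one avoidance cancel.
5. **Modeling** — PCA over per-ROI features, Wilcoxon on PC1 between
   cohorts, logistic regression `P(CR) = 1/(1+exp(−(a + b·PC1)))` with a
   ridge fallback under complete separation, and a marker correlation
   network.

Because clinical images cannot be redistributed, the package ships a
**synthetic tissue simulator** that emulates the study design end to end:
no-rejection (NR) ROIs with sparse, scattered immune cells; chronic
rejection (CR) ROIs with dense mixed immune aggregates; 12 bundled
phenotype profiles (11 immune + hepatocyte) over a 10-channel panel
(8 immune markers, collagen-1, iridium DNA); planted pairwise spatial
attractions; and exact ground truth (cell masks, phenotype labels,
expression draws) so every stage is tested against a known answer.

## Worked example

```python
import numpy as np
from imcscope import simulate, segment, neighborhood, model

# 1. simulate one chronic-rejection ROI and recover its cells
roi, truth = simulate.simulate_roi(simulate.cr_default_config(seed=11))
stack2x = segment.upscale2x(segment.remove_hot_pixels(roi.stack, 5.0))
labels2x = simulate.training_labels_from_truth(truth, seed=0)
clf = segment.train_pixel_classifier([stack2x], [labels2x], seed=0)
mask, cells = segment.segment_roi(roi, clf)
matches = segment.match_cells(truth.true_mask, mask)
print(f"{roi.roi_id}: {len(cells)} cells segmented "
      f"({truth.n_cells} planted, recall {100*matches['matched'].mean():.1f}%)")

# 2. test the planted Macrophage-2 / CTL-2 attraction
graph = segment.build_neighbor_graph(truth.true_mask, radius_px=4)
immune = truth.cells.set_index("cell_id")["immune"]
res = neighborhood.permutation_test(
    graph, truth.phenotype_of_cell, n_perm=5000, alpha=0.01, seed=0,
    phenotypes=sorted(set(truth.phenotype_of_cell[immune])), permutable=immune)
hit = res.query("phenotype_a == 'Macrophage-2' and phenotype_b == 'CTL-2'").iloc[0]
print(f"Macrophage-2 ~ CTL-2: {hit.observed_stat:.2f} neighbors/cell, "
      f"p_high = {hit.p_high:.2e} -> {hit.verdict}")

# 3. cohort modeling on per-ROI features (8 NR vs 24 CR)
feats, cohorts = simulate.simulate_cohort_features(8, 24, seed=1)
pca = model.pca_fit(feats, scale=True)
_, p = model.pc1_test(pca, cohorts)
lr = model.logistic_pc1(pca, cohorts)
print(f"PC1 explains {pca.explained_pct[0]:.2f}% of variance; "
      f"Wilcoxon NR vs CR p = {p:.1e}")
print(f"{lr.n_high_confidence}/32 ROIs classified with correct-class "
      f"probability >= 0.75 ({lr.n_outliers} outliers)")
```

Output:

```
CR-11: 380 cells segmented (380 planted, recall 100.0%)
Macrophage-2 ~ CTL-2: 1.21 neighbors/cell, p_high = 2.00e-04 -> interaction
PC1 explains 48.23% of variance; Wilcoxon NR vs CR p = 6.8e-05
29/32 ROIs classified with correct-class probability >= 0.75 (2 outliers)
```

Reading it: segmentation recovered every planted cell; Macrophage-2 cells
have on average 1.21 CTL-2 neighbors, far above any of 5000 label
permutations, so the pair is flagged as a spatial interaction; and on a
simulated 8-NR/24-CR cohort the leading principal component of per-ROI
marker medians separates the cohorts (rank-sum p ≈ 7 × 10⁻⁵) with most
ROIs confidently classified.

The same pipeline runs from the shell:

```bash
imcscope simulate --out run/sim --n-nr 2 --n-cr 2 --seed 7
imcscope run --config config.yaml     # full simulate→…→model run
```

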