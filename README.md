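# villaxis

Anatomical-axis cartography, immune allocation maps and in-situ perturbation
decoding for imaging-based spatial transcriptomics of the small intestine.

## The problem

Tissue-resident memory CD8 T (T_RM) cells in the small intestine split into
at least two functional states — differentiated effectors near the villus
tip and progenitor-like cells near the crypt — and their transcriptional
state is tightly coupled to where they sit in the tissue. Quantifying that
coupling from Xenium/MERSCOPE-style data requires a coordinate system for
the tissue itself, not just x/y pixel positions. `villaxis` provides that
coordinate system and the downstream statistics, for anyone analysing
per-cell spatial transcriptomics of villus-structured (or otherwise
repetitively structured) tissue.

## What it computes

**Three anatomical axes per cell.**

* *Longitudinal*: the arc-length fraction `s(c)/L` of the nearest point on
  the basal-membrane polyline (length `L`), in [0, 1].
* *Crypt–villus*: the Euclidean distance `d(c)` from the cell to the basal
  membrane, z-scored within each segmented villus:
  `cv(c) = (d(c) − μ_v) / σ_v`. Where morphology is poor, `cv` is instead
  predicted from 15 non-negative latent factors of the summed counts of each
  cell's 10 nearest epithelial/stromal neighbours (NMF + a pluggable
  regressor), then smoothed over the 150 nearest spatial neighbours.
* *Epithelial*: `epi(c) = mean_5NN-epithelial-dist / mean_5NN-any-dist ≥ 1`,
  z-scored over the sample and clipped at +3.

**IMAPs (immune allocation plots).** Each cell is placed at
`(cv, asinh(epi_clipped / w))`; weighted Gaussian KDEs over this plane show
where a population, a gene's transcripts (counts as weights) or a signature
(squared rank-based enrichment scores as weights) concentrates. Polygon
gates (villus top, crypt, muscularis) yield per-region counts, fractions and
log-normalized expression.

**Gradient screens and trends.** Spearman rank correlation of every gene
expressed in ≥ 5 % of a cell subset against each axis, with genes classed
positive/negative at |ρ| > 0.05; moving-average and penalized-spline (GAM)
expression trends along an axis, z-scaled for comparison.

**Proximity statistics.** k-NN spatial neighbour graphs, replicate-averaged
cell-type × cell-type interaction matrices (max-normalized with a 0.1
display threshold, or row-normalized), nearest-cell-type distance tables,
expression–distance Spearman correlations, and two-sample Kolmogorov–Smirnov
comparison of proximity distributions (similarity cut-off D = 0.08).

**Pooled-perturbation decoding.** sgRNA identities are read from pseudogene
barcode counts (7–8 hybridization sites landing on low-expression panel
genes). A cell is called perturbed only if it passes all four filters:
raw Cd8a+Cd8b1+Cd3e ≥ 3, at least one barcode count, membership in a CD8
T cell cluster, and ≤ 1 Muc2 transcript (guarding against goblet-cell
bleed-over). Group statistics use pairwise Welch t-tests on log-normalized
counts with Benjamini–Hochberg correction.

**Synthetic tissue generator.** A flat-geometry villus/crypt/muscularis
simulator with epithelial cells on the villus lining, log-linear
axis-dependent gene counts, designated null genes, biological replicates and
the barcode/contamination scenario — every axis and label is known
analytically, so each stage above is tested against ground truth.

## Worked example

```python
import villaxis as vx
from villaxis import axes, gradients, perturb
from scipy.stats import spearmanr

cfg = vx.SyntheticConfig(perturbation_design=vx.PerturbationDesign())
bundle, truth = vx.simulate(cfg, seed=1)          # 5,000 cells, 10 villi

aset = axes.compute_axes(bundle.cells, bundle.annotations["basal_membrane"],
                         bundle.villus_labels)
z = aset.values["crypt_villus"].dropna()
print(spearmanr(z, truth.cells.loc[z.index, "crypt_villus"]).statistic)
# 0.998  — geometric crypt–villus axis vs the generator's true height

cd8 = bundle.cells.cell_ids[bundle.cells.meta["cell_type"] == "CD8_T"]
counts = bundle.cells.counts.loc[cd8]
axis = aset.values.loc[cd8, "crypt_villus"].dropna()
screen = gradients.axis_correlation_screen(
    counts.loc[axis.index], axis,
    genes=gradients.expression_fraction_filter(counts))
print(screen.sort_values("rho")[["gene", "rho", "class"]])
#   gene     rho     class
#   Tcf7  -0.297  negative   (planted progenitor gradient, recovered)
# Slamf6  -0.256  negative
#    ...
#   Gzma   0.445  positive
#   Gzmb   0.497  positive   (planted effector gradient, recovered)

calls = perturb.call_perturbed_cells(bundle.cells, perturb.BarcodeDesign())
called = calls[calls["called"]]
print(len(called), called["sgrna"].value_counts().to_dict())
# 354 {'sgCd19': 118, 'sgThy1': 118, 'sgCxcr3': 118}
# decoding precision vs ground truth: 1.000
```

The same stages are available from the shell:

```sh
villaxis simulate --seed 1 --out sim/
villaxis axes --bundle sim/ --out axes.csv
villaxis run-all --seed 1 --out run/
```

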