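# Methods

## The mapping model

A query transcriptome is summarised as a pseudo-bulk profile (mean CP10K
log1p expression over QC-passing cells). For each spatially anchored
reference sample the sample Pearson correlation with the query is computed
on a selected gene set and attached to the sample's anchor vertex
(multiple samples on one vertex are averaged so the GP training set stays
well-posed). A Gaussian process with squared-exponential kernel
`k(u,v) = sigma_f^2 exp(-||x_u - x_v||^2 / (2 ell^2))` on 3D vertex
coordinates interpolates the anchored correlations to every vertex. The
training values are mean-centred before fitting and the mean is added back
to predictions, so a constant correlation field is reproduced exactly.
Distances are Euclidean in 3D, not geodesic: on a surface sampled densely
relative to `ell` the two are close, and Euclidean keeps the kernel exactly
positive definite; a geodesic mode is left as a config stub.

Static fields are clipped to [-1, 1] after smoothing (GP means can
overshoot the correlation range; the `clipped` flag records when this
happened). Dynamic fields are the signed per-vertex difference
perturbed - control of two static fields on the same mesh and metric, and
are bounded in [-2, 2] by construction.

Hyperparameters `(ell, sigma_f^2, sigma_n^2)` maximise the log marginal
likelihood via L-BFGS-B on log-parameters with analytic gradients,
multi-start (5 starts, seeded), `ell` bounded between the mesh mean edge
length and the mesh diameter and `sigma_n^2 >= 1e-6`. Cholesky failures
escalate jitter 1e-8 -> 1e-4 (x10 steps) before erroring. These are
numerical necessities; none of them is data-tuned.

## Lineage space

Cross-dataset gene selection uses canonical correlation analysis in the
orientation standard for cross-dataset single-cell integration: the shared
genes are the paired observations, each dataset's profiles are the
canonical variables. Genes are standardised within each dataset first, so
canonical correlations are invariant to per-dataset gene rescalings; both
covariance matrices carry a ridge (gamma = 1e-3, needed because profiles
are few). Canonical pairs come from the SVD of the whitened
cross-covariance; the per-gene score is the largest absolute canonical
variate loading over the first `n_components` (default 2) pairs, and the
`top_k` (default 500; 300 in the mapping pipeline) genes by score are
selected with ties broken by gene id.

"Adjusted expression values" for the joint PCA are per-dataset gene-mean
centred profiles: subtracting each dataset's own per-gene mean removes the
systematic offset between deep reference samples and single-cell
pseudo-bulks (the batch axis), leaving the lineage axis to dominate PC1/2.
PCA loadings are right-singular vectors with the largest-magnitude entry
of each loading forced positive; the decision boundary is a soft-margin
linear SVM (C = 1) in the PC1/PC2 plane fit on the labelled reference
scores, with the sign convention d > 0 = embryonic disc. Stage assignment
is the argmax Pearson correlation against per-stage references, ties
broken CS5 < CS6 < CS7 and flagged.

## The synthetic study

The generator emulates the study conditions end to end.

- **Mesh**: two spherical caps of equal rim radius (default 100 um): a
  hemispherical columnar-disc cap below the rim plane and a shallower
  amnion cap (height 0.35 x rim radius) above it. The union is convex, so
  the convex hull triangulation is watertight and single-component. Disc
  vertices split anterior/posterior by the tangential x axis; amnion
  vertices split distal/proximal at 0.6 x rim radius in cylindrical
  radius. Default 400 vertices.
- **Expression fields**: 10 marker gradients (logistic gates of the axis
  coordinates; anterior-disc-biased SOX2, broad POU5F1/NANOG, posterior
  TBXT, pan-amnion TFAP2A/TFAP2C and low heterogeneous ISL1, distal-amnion
  VTCN1/GABRP/HAND1), 1,990 region-independent background genes (lognormal
  levels), and 300 random-smooth genes: lognormal transforms of GP draws
  with length-scale 0.35 x rim radius — deliberately different
  hyperparameters and an independent seed stream from the mapping kernel,
  so smoothness in the data never certifies the fitted model by
  circularity.
- **Counts**: negative binomial with Var = m + m^2/theta, theta = 10;
  library sizes lognormal(log-mean 9.2, log-sd 0.3), i.e. ~10k counts per
  cell, a full-length Smart-seq-like depth. Spheroids default to 200 cells.
  Reference samples emulate multi-cell microdissected biopsies and pool 20
  cell-equivalents of library (`reference_pool_cells`), 8 samples per
  region: spatial reference data are not single cells, and this keeps the
  anchor profiles appropriately less noisy than individual query cells.
- **Perturbations**: convex archetype mixing — cell means are
  (1-lambda) x source-region archetype + lambda x target-region archetype;
  an optional per-gene boost models primitive-streak marker upregulation.
- **Stages**: CS5/CS6/CS7 field sets share background/smooth genes;
  amnion maturation markers scale 0.5/1.0/1.6 and each stage carries a
  40-gene stage-specific program (8x elevation), so global correlation can
  rank stages.
- **Image stacks**: spherical epithelial shells with ellipsoidal nuclei
  placed on a jittered Fibonacci lattice at mid-shell radius; major axes
  radial for `epi` (shell 18-30 um, nuclei 4.0 x 1.6 x 1.6 um) and
  tangential for `am` (shell 34.5-36 um, nuclei 4.0 x 1.2 x 1.2 um),
  orientation jitter 2 deg; per-nucleus channel intensities Gaussian
  around kind-dependent means with additive detector noise; voxels
  0.5 um isotropic by default.

What the generator does **not** emulate: real genome annotation or gene
counts, sequencing error, doublets, batch chemistry, feeder-cell
contamination, irregular nuclear shapes, optical point-spread or
segmentation errors (label masks are inputs by contract). Passing tests
therefore demonstrate the machinery is correct and calibrated on data
matching its assumptions — not that the biological conclusions transfer to
any real dataset.

## Preprocessing conventions

Normalization is counts-per-10,000 with natural log1p. QC keeps cells with
enough detected genes and total counts; thresholds are scale-dependent
(defaults 2,000 genes / 50,000 counts for deep full-length data; the
synthetic pipeline uses 500 / 4,000 to match its ~10k-count cells), and
failing cells are flagged, not dropped. HVG selection ranks normalized
variance (ddof = 1) with deterministic ties. Differential expression is a
two-sided Wilcoxon rank-sum per gene (exact for small ties-free groups)
with Benjamini-Hochberg adjustment; fold changes use
log2((meanA + 0.01) / (meanB + 0.01)) on the normalized scale, and calls
use q < 0.05, |log2FC| > 1. Dunn's post-hoc test after Kruskal-Wallis uses
pooled mid-ranks with tie correction and Bonferroni adjustment.

## Morphometrics conventions

Orientation is the angle between the principal second-moment axis of a
nucleus (in physical um coordinates, so anisotropic voxels are handled)
and its radial direction to the spheroid centroid, folded to [0, 90] deg;
nuclei under 5 voxels are skipped and near-isotropic nuclei (eigenvalue
ratio < 1.1) are flagged degenerate and excluded from the
basolateral/apical ratio (threshold 45 deg, infinite ratio reported as a
sentinel). Thickness casts rays from the centroid along a golden-spiral
direction lattice, samples the tissue mask at half-voxel steps in physical
space and takes the distance between first and last crossing plus one
step (midpoint-crossing correction — without it both surface estimates are
biased inward by half a step). Intensity ratios guard denominators with
eps = 1e-6; intensity sums accumulate in float64.

## Validation design

`spheromap.experiments` holds the seeded validation experiments shared by
the tests, the analysis drivers and `scripts/acceptance.py`. The oracles
are deliberately independent code paths: dense `np.linalg.solve` for GP
posteriors, eigendecomposition square roots for CCA, an SLSQP dual QP for
the SVM, exhaustive rank-assignment enumeration for Mann-Whitney, and
naive per-entry loops for normalization/pseudo-bulk/z-scores/BH.
Problem sizes (400-vertex mesh, 2,300 genes, 200-cell queries, 100 Monte
Carlo runs per recovery experiment, 10,000 replicates for the Shapiro-Wilk
calibration) are the package's default synthetic study; the full
validation battery runs in about 90 s.

The dynamic-map null check compares the mean |delta| of control-vs-control
field pairs to the replicate Monte-Carlo standard error of the static
field (mean per-vertex SD over 40 replicate maps): for pure sampling noise
E|delta| ~ 1.13 x SD, so a ratio above 3 would indicate a systematic
artifact rather than noise.

## Known limitations

- Euclidean kernel distances ignore surface topology; two vertices close
  through the interior count as neighbours.
- The similarity gene set defaults to CCA-selected genes; a
  control/perturbed pair alone has too few profiles for CCA, so dynamic
  maps fall back to reference HVGs.
- The SVM boundary lives in PC1/PC2 only, matching the 2D lineage plots;
  structure in higher PCs is ignored.
- `assign_stage` assumes stage references share the query's gene universe;
  no cross-species or cross-annotation mapping is attempted.
- Ray-cast thickness assumes a star-convex epithelium around the centroid;
  folded or open tissues need the junction-point mode.
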