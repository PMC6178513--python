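# Methods

This note documents the models and procedures implemented in `mammocad`,
the parameter defaults and why they were chosen, the numerical decisions,
and what the synthetic validation does and does not show.

## Enhancement: entropy-maximization fusion

The enhanced mammogram is a per-pixel selection between the original
image `I` and its CLAHE version `I_c`: the output takes the value of
whichever source has the larger local Shannon entropy

    ENT(x, y) = − Σ_{k=0}^{255} p_k log2 p_k ,

where `p_k` is the 256-level histogram of the `w × w` window centered at
`(x, y)` (default `w = 5`, borders reflected, `0·log 0 := 0`).  Entropy is
a proxy for local detail: where CLAHE has created structure the fused
image follows it, and in flat regions the tie-break keeps the original
value so CLAHE's noise amplification is not imported.  CLAHE defaults are
clip limit 0.01 with an 8 × 8 tile grid (both configurable); the fusion
rule itself has no tunable parameter beyond the window.

Entropy values are bounded by `log2(w²)` and the implementation is tested
against a brute-force per-window histogram on random images.

## Breast mask and pectoral-muscle suppression

The breast field is the largest 8-connected component above the Otsu
threshold, holes filled.  Pectoral suppression looks inside the top
corner rectangle (top 40% of rows, near 50% of columns on the pectoral
side, auto-detected from top-half intensity mass if not given) for the
per-row column of maximum horizontal Sobel gradient.  Three robustness
measures, adopted after the plain least-squares variant proved fragile,
define this stage:

- gradient points are only accepted inside the breast interior (mask
  eroded by 4 px), so the skin–air boundary can never pose as a muscle
  edge;
- the line through the points is fitted robustly — Theil–Sen slope,
  median intercept, then least squares on the < 4 px inliers — because a
  handful of mass-border points at high leverage can flip an ordinary
  fit;
- the fit is accepted only if the strong-gradient rows cover at least
  30% of the rectangle and stay collinear; otherwise the image is
  returned unchanged with a warning.  A muscle wedge produces a long
  straight boundary; masses and texture do not, and a no-op is the safe
  failure mode.

Pixels on the muscle side of the accepted line (plus a 1.5 px margin
covering the anti-aliased boundary) are set to zero.

## SOM segmentation and candidate filtering

Pixel features are the raw 3 × 3 neighborhood intensities (9 values,
center included, borders reflected); intensities are already in [0, 1]
so no rescaling is applied.  The map is a 2 × 2 node grid (M = 4,
unit spacing) — the smallest topology that still exercises the spatial
neighborhood kernel.  Training is online: 20,000 pixels sampled with
replacement (seeded), winner by minimum Euclidean distance, update

    W_i ← W_i + η(t) · exp(−‖m_c − m_i‖² / 2σ²(t)) · (f − W_i),

with `η(t) = 0.5·0.01^(t/T)` and `σ(t) = 1.0·0.01^(t/T)` decaying to 1%
of their initial values over the run.  Weights initialize uniformly in
[0, 1].  The decay form, grid, and initialization are package choices;
assignment is verified against brute-force nearest-weight search.

Masses are bright, so the cluster of interest is the one with the
highest mean image intensity.  Its 8-connected components are kept when
their pixel count lies in the PLT band; the 450–31,500 px band is the
shipped default, appropriate for ~1024 × 1024 small-format images, and
both bounds are plain parameters for other formats.  Candidates become
sparse ROIs: tight bounding-box crops with non-candidate pixels set to
exactly zero, zero-padded symmetrically up to the 25 × 22 px minimum the
descriptor stage requires.

## The curvelet transform

The 17-band decomposition tiles the 2-D FFT plane with non-negative
windows whose squares sum to one everywhere (a tight frame): a low-pass
band bounded by a Meyer-type raised-cosine ramp of the max-norm radius
(flat below ¼ of Nyquist, zero above ½), and a detail corona split into
16 angular wedges by raised-cosine crossfades of the orientation angle
taken modulo π, so each wedge pairs antipodal directions and the spatial
coefficients are real.  Two details matter numerically:

- on even grids the Nyquist row/column aliases `−ω` onto itself while
  the angle flips; each window is symmetrized under frequency negation
  (averaging squared windows), which restores exact realness without
  breaking the partition of unity;
- subbands are kept at full resolution rather than wrapped to decimated
  rectangles.  This trades memory (17× the image) for an exactly
  invertible, aliasing-free transform whose coefficient maps are in
  pixel registration with the ROI — which the descriptor exploits
  directly.  Measured round-trip error is at machine precision (~1e-16
  relative) and the Parseval ratio is exactly 1 within 1e-12.

Odd dimensions are reflect-padded to even before the FFT; the inverse
crops back.

## Sparse uniform-LBP descriptor

A sparse ROI's subbands are first restricted to the mass support: the
full-resolution coefficient maps are in registration with the patch, and
coefficients over the zero background describe the background, not the
mass, so they are set to exactly zero.  This is what makes the subbands
sparse in practice — FFT-domain filtering spreads energy everywhere, so
no magnitude threshold alone recovers sparsity (measured: 0% of windows
rejected at relative tolerances up to 1e-2 on unmasked bands).  The
per-band tolerance `tol = tol_rel · max|band|` (default `tol_rel =
1e-6`) remains as a guard against floating-point residue.

The lookup table then scans every fully-interior 3 × 3 window of the
masked band: a window with more than 2 nonzero values is *foreground*
(the `count = 2` boundary case is treated as background — the
conservative reading of a strict `> 2` rule).  At foreground centers an
LBP code is computed over the full window — background neighbors
participate in the comparison — with bit `p` set when the p-th ring
neighbor (counter-clockwise from east, R = 1, no interpolation) is `≥`
the center.  Codes with more than two circular 0↔1 transitions are
discarded; the remaining codes fill the 58 uniform-pattern bins
(ascending pattern order), normalized by the retained count so ROIs of
different sizes are comparable.  Concatenating the 17 per-band
histograms gives the 986-vector.

The fast vectorized path is verified bin-for-bin against a naive
per-pixel loop on random sparse bands; the fraction of rejected windows
is shape-dependent by construction (~40–65% on the synthetic ROI pool)
and is reported per ROI as both rejected window rows and zero
coefficients, since the two counts answer different bookkeeping
questions.

## Classification and evaluation

The ANN is a 986-input MLP with one hidden layer of 20 logistic units
(hidden size configurable; chosen small since the histograms are already
compact), adam, learning rate 0.01, at most 800 epochs.  A third of the
training material is held out for early stopping; below 60 training
samples that third is too small to be informative and the network
instead trains to convergence.  The SVM is RBF-kernel (C = 1, scale
gamma) scored by its decision function; KNN uses k = 5 with the positive
neighbor fraction as score.  Operating thresholds are 0.5 for
probability scorers and 0 for the SVM decision value.

Cross-validation is 3-fold and *group-aware*: every augmented copy of a
patch carries the source patch's group id, groups are shuffled
(seeded) and split into three nearly equal folds, and a leakage guard
asserts that no group appears in two folds.  This is stricter than
splitting individual patches and keeps reported numbers honest; the
augmentation transforms (horizontal flip at factor 2; plus vertical flip
and 180° rotation at factor 4) preserve the sparse support exactly.
Reported metrics: per-fold and mean sensitivity, specificity, accuracy
and trapezoidal ROC AUC (verified equal to the Mann–Whitney statistic),
plus the detection-level rates TPR = TP/#lesions and FPPI = FP/#images.

## Synthetic data

Phantoms emulate: a breast half-disc anchored at the chest wall over an
exactly-zero background, an intensity ramp (0.38 falling to 0.30),
correlated texture (Gaussian noise smoothed at σ = 4 px, amplitude
0.03), i.i.d. acquisition noise (σ = 0.02 default), an optional pectoral
wedge at intensity 0.8, and masses with star-perturbed boundaries
`r(θ) = r0(1 + irregularity·Σ_{k=2..5} a_k cos(kθ + φ_k))`, amplitudes
drawn once per mass and bounded so the radius stays positive.  Default
conditions: 256 × 256 px, two disjoint masses of radius 12–30 px
(≈ 450–2,800 px areas, inside the default PLT band), contrast 0.4.
Labeled ROI pools pair bright smoothly-shaded irregular masses (label 1,
contrast 0.4) against faint textured patches with the same sparse
support machinery (label 0, contrast 0.1).

What the phantoms do **not** emulate: calcification clusters, spiculated
margins, overlapping dense parenchyma, compression artifacts, or
scanner-specific noise.  Consequently the synthetic validation
demonstrates that the pipeline's machinery is correct and that the
descriptor separates easy mass/non-mass contrasts essentially perfectly;
it says nothing about sensitivity or FPPI on clinical data, where class
overlap is far larger.

## Degenerate inputs and tie-breaks

Constant images: CLAHE returns them unchanged, local entropy is zero,
cluster assignment collapses to one label.  Fusion ties keep the
original pixel.  BMU ties go to the lowest node index.  All-zero bands
yield all-zero histograms (no retained codes to normalize by).  An
all-zero image is rejected by the breast-mask stage.  Empty candidate
lists are valid outputs of PLT filtering.

## Problem sizes

Defaults throughout (256² phantoms, 20,000 SOM samples, 100 + 100 ROI
pools, 3 cross-validation folds) were chosen so a full pipeline run is
interactive on a single core; all are parameters, and every stage scales
to larger images by passing larger values.
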