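# Methods

## Problem setting

A MALDI-MSI dataset is a set of centroided mass spectra indexed by integer
grid coordinates (40–50 µm pixels, negative ion mode, m/z 300–1000 at a
nominal resolving power of 140,000). A pathologist annotates an adjacent
H&E-stained section with Tumor / Non-tumor / Background regions; because
the sections are adjacent and imaged separately, the annotation raster is
misaligned with the MSI grid and must be coregistered before the labels can
be transferred to pixels. The analysis goal is a classifier that assigns
each pixel of an *unseen* tissue section to Tumor, Non-tumor or Background,
plus a ranking of the ions that drive the decision.

## Spectral preprocessing

**Recalibration.** Orbitrap-type mass errors are multiplicative and drift
smoothly across an acquisition. Each pixel's error is estimated as the mean
observed ppm deviation of two reference ions (m/z 311.2950 and 885.5493)
matched within 30 ppm; a least-squares plane ppm(x, y) = a·x + b·y + c over
all matched pixels supplies the estimate for pixels where neither calibrant
was found. The m/z axis is then divided by (1 + ppm·10⁻⁶) — divided, not
shifted, because ppm errors scale with mass. The fit is exact up to the
per-centroid jitter; on synthetic drifts of up to ±25 ppm the plane is
recovered to well under 0.5 ppm and the post-correction median reference-ion
error is a fraction of a ppm.

**Tissue detection.** A pixel counts as tissue when it shows signal within
30 ppm of m/z 885.5493 (PI(38:4), present throughout tissue) above a
configurable intensity floor (default 0 — any recorded centroid counts,
appropriate for centroided data where the noise floor was already applied
at acquisition).

**Mean spectrum and peak picking.** Tissue spectra are accumulated on a
log-spaced axis with 2 ppm bins (constant relative width, matching the
instrument's resolution behavior) and averaged. The mean spectrum is
smoothed with a 2nd-order Savitzky–Golay filter over a 21-point window with
Gaussian point weights, σ = (window − 1)/6; the filter is implemented as a
weighted local polynomial fit, so constants and quadratics pass through
unchanged and window truncation handles the edges. Local maxima above
0.001 of the global maximum are kept greedily in descending intensity with
a 20 ppm minimum mutual separation, and each centroid is refined by
three-point parabolic interpolation. Peaks are picked once on the
**cohort-pooled** mean spectrum so that every dataset shares one feature
space — a prerequisite for training on some sections and testing on others.
Feature extraction then records, per pixel and peak, the maximum centroid
intensity within ±10 ppm (the expected peak width at resolving power
140,000 is ≈7 ppm FWHM at m/z 1000).

## Coregistration

PCA is computed on the mean-centered **log10(v + 1)** feature matrix. The
log transform matters: on raw intensities a handful of high-abundance ions
dominates the first component, whereas on log intensities the
tissue-versus-background contrast — shared by every ion — dominates, which
is what makes the PC1 score image usable as a tissue outline. Component
signs follow a fixed convention (largest-magnitude loading positive), and
the tissue mask is the Otsu split of the PC1 image, oriented so the tissue
side has the higher mean total ion intensity (and therefore invariant to
the component's arbitrary sign).

The annotation mask is aligned to the MSI grid with a similarity transform
(isotropic scale 0.5–2.0, rotation ±15°, translation up to 25% of the grid)
chosen to maximize the Dice coefficient between the transformed
histology-frame tissue mask and the MSI tissue mask. All non-Background
labels count as histology tissue, including Unlabeled regions, which in
annotated sections are unlabelled *tissue*. The objective is evaluated by
inverse-map nearest-neighbor warping (hole-free at any scale). Because the
Dice landscape of quantized binary masks is multi-modal, the search is
multi-start: a coarse grid over rotation (3° steps) and scale (0.05 steps)
with centroid-seeded translation, followed by two shrinking local
refinement rounds around each of the five best coarse cells. Equal-Dice
ties resolve deterministically to the smallest |rotation|, then the
smallest translation, then the scale nearest 1 — the least aggressive
transform — so repeated runs give byte-identical results. A best Dice below
0.7 raises a registration error rather than silently accepting a bad
alignment. Labels are transferred by nearest neighbor (labels are
categorical; interpolation would invent classes), with out-of-frame pixels
becoming Unlabeled.

On synthetic misalignments the planted transform is recovered to within 1°,
0.05 scale and 1 pixel provided the offset magnifies MSI → histology (scale
≥ 1, the realistic direction: the scanned H&E frame is the finer raster)
and leaves the section inside the frame. When the annotation raster is
*coarser* than the MSI grid, double nearest-neighbor quantization at class
boundaries caps label-transfer agreement below that level regardless of the
estimator — an information limit of the rasterized-mask representation, not
of the search.

## Classification and the scaled-probability rule

Feature vectors are normalized by log10(v + 1) (the +1 offset handles the
zeros that a max-in-window extractor necessarily produces) and then scaled
to unit Euclidean norm per spectrum, removing per-pixel ionization
efficiency differences. Three binary logistic problems are trained on the
labelled pixels: Tumor vs Non-tumor + Background, Tumor + Non-tumor vs
Background, and Non-tumor vs Tumor + Background. Each fit minimizes the
L2-penalized binomial negative log-likelihood (λ = 10⁻², intercept
unpenalized) by damped Newton/IRLS iteration from a zero start, converging
when the gradient max-norm falls below 10⁻⁶; the penalty is required
because pixel classes are frequently linearly separable, and the fits are
verified in the test suite against brute-force grid minimization of the
identical objective and against an independent solver.

Per-pixel raw scores are s_T and s_N, the sigmoids of the Tumor and
Non-tumor problems, and s_B = 1 − sigmoid of the tissue-vs-background
problem (Background as the complement of Tissue). The *scaled
probabilities* are p_k = s_k / (s_T + s_N + s_B); a pixel is assigned the
argmax class only when its scaled probability exceeds 0.5 and is otherwise
Unclassified. Under this construction the three values sum to one, at most
one class can exceed the threshold, and an all-zero score triple (which
sigmoids cannot actually produce) is defined to give the uniform
distribution, hence Unclassified. No feature standardization is applied
beyond the stated normalization, so coefficients remain comparable across
ions; for reporting they are oriented so that **negative means upregulated
in tumor**, and ranked by magnitude with ties broken by ascending m/z.

## Validation

Cross-validation is leave-one-group-out at the *dataset* level: each fold
withholds one complete tissue section, trains on the rest, and classifies
the held-out section's labelled pixels. This measures transfer to unseen
samples; pixel-level k-fold would leak within-section correlation and
overstate performance. Confusion counts are pooled over folds (per-fold
counts are retained for inspection, but no per-fold standard deviation is
reported — folds are entire heterogeneous sections, not exchangeable
replicates). Unclassified labelled pixels form their own category: they
appear in the class totals but in none of the three metric formulas, which
use only TP/FN/TN/FP with Tumor as positive. The variant that counts
Unclassified tissue pixels against the model is computed alongside
(`accuracy_incl_unclassified`); with the default threshold the two rarely
differ.

Area-based predictive power consumes externally supplied false-positive and
false-negative region masks (in production, a validating pathologist's
annotations; in tests, masks synthesized from ground truth) and reports
1 − (FP area + FN area)/tissue area together with a relative-area confusion
table.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the pipeline
relies on, with defaults chosen as the package's reference study
conditions: 10 datasets of 32×32 pixels; 200 true peaks (including both
reference ions) with ≥100 ppm mutual separation, log-uniform baseline
intensities spanning two decades; 5 tumor-upregulated ions planted in the
lipid range (m/z 600–900) and one tumor-downregulated
cholesterol-sulphate-like ion at m/z 465.304; a mean class effect of 1.0 in
log10 units (10-fold); multiplicative log-normal intensity noise with CV
0.2 plus 1 ppm centroid jitter; a drift plane of (0.1, −0.05, 5.0) ppm; an
irregular elliptical tissue blob (low-order radial lobes, as real sections
have — a perfect ellipse would make rotation unidentifiable) containing a
tumor sub-region of ~40% of the tissue area; and an annotation mask
exported through a (dx=2, dy=−3, 4°, ×1.1) misalignment with 30% of tissue
pixels relabelled Unlabeled, mimicking deliberately sparse annotation.
Background pixels carry a handful of low-intensity noise centroids, never
near the reference ions. The peak panel is seeded independently of the
per-dataset noise seed so an entire cohort shares one panel while
geometry and noise vary; dataset i of a cohort uses seed base + i, and
identical configurations are bit-identical.

What the generator does **not** model — isotope envelopes, adducts, matrix
clusters, detector saturation, tissue sub-classes (glands, muscle, keratin
pearls), spatial intensity texture within a class, or non-rigid section
deformation. Passing tests therefore demonstrate that the pipeline recovers
what it is designed to recover under its own assumptions, not that those
assumptions hold for any particular instrument or tissue; on real data the
registration Dice floor and the Unclassified rate are the first diagnostics
to watch.

## Numerical choices and degenerate inputs

Scaled probabilities and Newton fits are computed with numerically stable
sigmoid/log-sum-exp forms; the Newton step is damped by halving until the
penalized loss does not increase. A constant PC1 image, a zero-variance
feature matrix, an empty tissue mask, a single-class training fold, a fold
missing one of the three classes, and zero metric denominators all raise
typed errors naming the offending quantity rather than propagating NaNs.
Flat spectra yield an empty peak list with a warning. All-zero feature rows
survive normalization as zero vectors and are flagged. Problem sizes in the
test suite (32×32 grids, 10-dataset cohorts, 200 peaks) are the package's
reference conditions; they keep the full study in the tens of seconds on a
single core while leaving every recovered quantity far from its noise
floor.
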