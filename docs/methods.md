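# Methods

This note documents the models and procedures implemented in `lucad`,
the defaults chosen where the classical CAD literature leaves choices
open, and what the synthetic phantom validation does and does not show.

## Scope and data model

Processing is strictly per 2D slice: a `CTSlice` is one gray-level
raster with isotropic physical pixel spacing (mm). Intensities are
normalized per slice by min–max to [0, 1]; a constant slice maps to all
zeros by convention. No Hounsfield calibration or windowing is applied —
the lung-extraction thresholds below are defined on the min–max scale of
the *enhanced* image, not on HU. When a DICOM file carries no
`PixelSpacing`, 0.7 mm is assumed (a 512 px slice spanning a ~358 mm
chest field of view); the spacing matters because the detection radius
bands are specified in millimetres. Coordinates are 0-based (row, col).

## Stage I: enhancement and lung volume extraction

The enhancement chain is median filter → Laplacian sharpening →
histogram equalization, in that order: denoising precedes
differentiation, and equalization runs last so the fixed extraction
thresholds always see contrast-normalized input. Defaults: 3×3 median
window, sharpening `out = clip(in − 0.5·L(in))` with the 4-neighbour
Laplacian and reflect padding, 256 equalization bins. The equalization
map is the standard CDF transform and is monotone nondecreasing.

Lung extraction (LUVEM) marks pixels with enhanced intensity strictly
between 0.25 and 0.65 as candidate lung — after equalization the lung
fields sit in this mid-dark band while soft tissue and bone exceed it —
then (1) removes every candidate component 4-connected to the image
border (background air and edge artifacts), (2) erodes with a disk of
radius 2, dilates with a disk of radius 4, and fills holes. Hole
filling is what restores nodules and vessels, which are brighter than
the band and would otherwise be cut out of the lung interior. The
erode<dilate pairing recovers area lost to erosion and bridges small
gaps at the cost of ~2 px of boundary inflation, negligible at lung
scale. Degenerate inputs produce an empty mask with a warning rather
than an exception so batch runs survive. The Otsu baseline
(`otsu_extract`) takes the below-threshold side of a global Otsu split
and applies the same border/morphology steps for comparability; on
phantoms with bright border artifacts its Jaccard against truth is far
below LUVEM's.

## Stage II: candidate detection and SOM segmentation

Candidates come from a circular Hough transform on the Canny edge map of
the enhanced slice, restricted to the lung mask. Radius search bands are
3–12, 10–20 and 15–45 mm, converted to integer pixel radii rounded
outward so no band collapses at coarse spacing. Accumulator scores are
perimeter-normalized (1.0 = a complete circle of edge pixels); the
default acceptance threshold is 0.3. The Canny scale is σ = 2 px: at
σ = 1 roughly a third of lung pixels register as texture edges after
sharpening and equalization, and spurious votes drown genuine peaks. Per
radius the top 10 accumulator peaks are examined. Greedy
non-maximum suppression keeps a candidate if its center is at least
max(5 px, smaller radius of the pair) from every kept center, so large
circles suppress their own off-center echoes. Whether the printed band
limits denote radii or diameters is ambiguous in the source literature
(the dataset bins are diameters); they are implemented literally as
radii and are configurable.

Each candidate gets a square ROI of side 2·⌈1.5·r⌉+1 (min 9 px, shifted
inward at borders). A 1D-chain SOM with 4 nodes is trained *on the
ROI's own pixels* — feature = (intensity, 3×3 mean) — for 20 epochs with
exponentially decaying learning rate 0.5→0.01 and Gaussian neighbourhood
radius 2→0.1. The final neighbourhood must be well below 1: at 0.5 the
inter-node coupling exp(−1/2σ²) is still ≈ 0.14 and a 2-node map never
decouples its prototypes. Prototypes are initialized from sampled
training vectors, sorted by intensity; training is seeded and
bit-reproducible. The nodule cluster is the node with the highest mean
intensity among those present in a 3×3 window at the candidate center;
clusters whose mean intensity lies closer to the nodule cluster's than
to the darkest cluster's are merged (boundary pixels form their own
mixed cluster and would otherwise cost a one-pixel ring of every
segmentation), and the mask is the 8-connected component at/nearest the
ROI center, holes filled. Per-ROI training adapts the map to local
contrast, which is what keeps very small nodules segmentable.

## Stage III: the 123-feature vector and PCA

Ordered layout: SSF (6) — mean, standard deviation, variance, skewness,
kurtosis, 256-bin histogram entropy in bits; population moments, with
skewness = kurtosis = 0 on zero-variance samples so vectors stay finite.
SBF (16) — area, perimeter, circularity 4πA/P², eccentricity, solidity,
extent, equivalent diameter, major/minor axis, aspect ratio, convex
area, convex perimeter, convexity, compactness P²/A, and the mean and
standard deviation of boundary-to-centroid radial distances (the
spiculation signal). Perimeters use the 4-direction Crofton estimator,
which is nearly unbiased on rasterized smooth shapes (the common
step-counting estimator inflates a disk's perimeter enough to push its
circularity to 0.91). GTF (88) — 22 Haralick-family descriptors of the
symmetrized, normalized gray-level co-occurrence matrix (16 equal-width
gray levels on [0,1], displacement 2 px) for each of the four angles,
concatenated angle-major. The descriptor list extends Haralick's 14
with dissimilarity, autocorrelation, maximum probability, inverse
difference and its two normalized variants, and a maximal-correlation
proxy (square root of the second eigenvalue of the GLCM transition
form); degenerate matrices fall back to correlation = 1 and information
measures = 0. TEF (13) — relative energies of the 12 detail subbands
(H, V, D at levels 1–4) plus the level-4 approximation of a Daubechies-2
decomposition with reflect extension; they are nonnegative and sum to 1.

SSF is computed on intensities inside the nodule mask, SBF on the mask,
GTF/TEF on the masked ROI cropped to the mask's bounding box (expanded
to ≥ 16 px so four decomposition levels are defined). Masking before
texture computation introduces an artificial boundary edge; it is
applied identically to every nodule and therefore cancels in
class comparisons.

PCA standardizes columns (the features mix px², bits and ratios;
zero-variance columns pass through with scale 1), retains the
top-variance components, and fixes each loading's sign so its
largest-magnitude entry is positive, making fits bit-reproducible. The
retained count follows the pattern-count heuristic
⌊min-class-size × split ⁄ 3⌋ (≥ 1): e.g. 17 components when the smaller
class has 104 patterns and the data are split in half. In
cross-validation the reducer is fit on the training fold only; a
`pca_global` switch reproduces protocols that fit the reducer once on
all data before validation (a form of leakage, provided only for
comparison).

## Stage IV: PNN classification and evaluation

The PNN stores every training vector (one pattern unit each) and scores
a query by the class-wise *mean* of Gaussian kernels; averaging rather
than summing makes scores prior-free so the minority class is not
dominated by pattern count (a `class_weight='prior'` switch restores
prevalence weighting). σ is the only free parameter; with `sigma='auto'`
it maximizes leave-one-out training accuracy over a 10-point log grid
from 0.05 to 5, ties to the smaller σ, recorded per fold in the run log.
An exact posterior tie resolves to *benign* — a deliberate convention of
favouring the non-cancer call only under perfectly balanced evidence.
As σ→0 the classifier approaches 1-nearest-neighbour; as σ→∞ the
posterior approaches the class priors (uniform under mean scoring).

Evaluation: malign is the positive class throughout. The six criteria
(Acc, Sen, Spc, PDV, NDV as percentages, F1 as a fraction) are kept at
full precision internally and displayed at 2 decimals with half-up
rounding; zero-denominator metrics are reported as null, never as 0 or
100. ROC/AUC uses a threshold sweep with trapezoidal integration, which
equals the normalized Mann–Whitney U statistic (asserted against an
independent pairwise-rank oracle in the tests). Leave-one-out
cross-validation runs at nodule level, refitting PCA and the PNN per
fold; size-stratified reports partition at <10 / 10–20 (both bounds
inclusive) / >20 mm, chosen so the band matrices always sum to the
overall matrix.

## The synthetic phantom

The generator emulates the structure of a clinical slice: a bright body
ellipse (0.75) on dark air (0.05), two dark lung fields (0.15 with
texture noise σ 0.02), 5–15 bright vessel segments (0.6), and circular
nodules (0.55) of 3–65 mm diameter. Malignancy is encoded through the
two cues that distinguish the classes both radiologically and
statistically: benign nodules are round with a smooth outward-feathered
border and low internal noise (σ 0.01); malign nodules have a
star-convex boundary perturbed by ≥ 8 random-phase harmonics at 28%
relative amplitude, and higher internal noise (σ 0.06). The benign edge
is feathered *outward only* so that internal intensity variance reflects
the internal-noise contrast between the classes rather than edge
blurring. Nodules are placed ≥ 8 px inside the lung boundary
(intraparenchymal): juxtapleural nodules would be severed from the lung
field by LUVEM's erosion, which is a genuine limitation of
threshold-plus-morphology extraction, not of the generator. The default
cohort emulation is 104 benign + 116 malign nodules in size bins
75/65/80 across <10/10–20/>20 mm. Everything is driven by one integer
seed and is bit-reproducible.

What phantom results show: that every stage works mechanically, that the
pipeline recovers a planted shape+texture malignancy signal end to end
(≥ 80% LOOCV accuracy on a 60-nodule cohort; 95.0% in the shipped
example), and that segmentation/detection accuracy claims hold under
known geometry. What they do not show: performance on real CT, where
attenuation physics, partial-volume effects, juxtapleural and
ground-glass nodules, and annotation noise all matter. Published
accuracies from clinical cohorts are not reproducible from synthetic
data and are not claimed.

## Problem sizes and numerical conventions

Tests and the shipped examples use 192–320 px slices (spacing 0.7 mm)
and cohorts of 8–60 nodules — large enough that every stage operates in
its intended regime while the full suite runs in about a minute. The
512 px default of `PhantomSpec` matches clinical raster size and is used
by the CLI. Determinism: identical (input, seed) pairs give identical
outputs at every stage; there is no unseeded randomness. Ties and
degenerate cases are fixed conventions rather than errors wherever a
batch run must survive them (empty lung mask → warning; uniform ROI →
empty segmentation with warning; constant sample → zero moments).

## Known limitations

* Single-slice 2D only; no volumetric context, no 3D features.
* Juxtapleural nodules are excluded by construction of LUVEM.
* The 16 shape and 22 texture descriptor identities are fixed by this
  package's convention; other CAD implementations with the same family
  counts may choose different descriptor sets.
* The spiculation and noise effect sizes of the phantom are generator
  parameters; classification difficulty on phantoms is controlled by
  them, not discovered.
* Histogram equalization assumes the lung fields dominate the dark end
  of the slice histogram; unusual fields of view could shift the
  (0.25, 0.65) band off the lungs.
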