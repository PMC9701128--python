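# Methods

`hemseg` detects hemorrhages (HEs) in color fundus photographs by a
five-stage pipeline: green-channel enhancement, matched-filter seed
extraction, image calibration, smart-window adaptive thresholding (SWAT)
segmentation, and SVM classification of hand-designed features. This note
records the model, its assumptions, the parameter choices, and the known
limitations, as implemented here.

## Model and assumptions

The central assumption is photometric: **a hemorrhage is a compact dark
region surrounded by brighter retina** in the green channel. Everything
else in the pipeline is machinery for making that assumption hold in the
hard cases — lesions adjoined to vessels (which are also dark) and lesions
at the field-of-view (FOV) rim (where the surround is the near-black
camera background rather than bright retina).

### Enhancement

The green channel is enhanced by three steps, in order:

1. **CLAHE** (contrast-limited adaptive histogram equalization), normalized
   clip limit 0.01, 8×8 tile grid.
2. **Gradient-adaptive gamma correction.** A single per-image gamma is
   chosen from Sobel statistics: with `m` the mean normalized intensity and
   `g` the mean normalized gradient magnitude,
   `gamma = clamp(log 0.5 / log(m + w·(1−g)), 0.4, 1.5)` with gradient
   weight `w = 0.2`. Dark, low-gradient images receive gamma < 1
   (brightening); a zero-gradient image falls back to gamma = 1 exactly.
   The rule is monotone in intensity, so ordering of gray levels is
   preserved.
3. **Fuzzy unsharp masking.** Per 3×3 window, detail = center − median;
   the amplification weight ramps from 0 below a noise floor (4 gray
   levels) to 1 at an edge scale (20 gray levels), so noise-scale
   fluctuations are barely amplified while true edges sharpen at full
   strength (0.7).

### Seed points

An isotropic **inverted-Gaussian matched filter**
`k(r) = 1 − exp(−r²/2σ²)`, shifted to zero mean, correlates maximally at
the centers of dark blobs of scale ≈ σ. The kernel is deliberately
blob-matched rather than oriented/vessel-matched: vessel responses are
wanted at this stage (they carry lesions attached to them) and are broken
afterwards by a morphological opening (disc radius 4).

The response map is thresholded by a **co-occurrence (GLCM) entropy
criterion**: the response is quantized to 256 levels, a symmetric GLCM is
built from horizontal+vertical unit offsets, and the threshold minimizes
the negative sum of the Shannon entropies of the two homogeneous quadrants
(both levels ≤ t, both levels > t), scanning thresholds successively and
keeping the first minimum. The objective is a swappable callable. The
returned threshold is mapped back to the input's own gray scale.

The pipeline runs the filter at **two scales, σ ∈ {6, 12}** (kernel radius
≥ 2σ), thresholding and opening each scale separately and concatenating
the per-scale component lists. A single mid-range σ = 8 seeded only ~92%
of planted lesions across the configured radius range (10–22 px): small σ
misses large lesions whose centers look locally flat, large σ merges
neighboring structures. Per-scale component lists (rather than a mask
union) keep a fine-scale core's tight bounding box even when the coarse
scale merges it into a neighbor. Components smaller than 5 px² are
dropped.

A note on degenerate inputs: the percentile-like entropy threshold always
retains the strongest response tail, and a matched filter applied to pure
noise produces σ-scale correlated excursions. A featureless image
therefore yields clutter seeds, not zero seeds; clutter is rejected later
by the classifier. A constant image raises a degenerate-histogram error.

### Calibration

The **retinal mask** is Otsu-binarized from the median-filtered
(disc radius 15) raw green channel; the largest component is kept, holes
filled, and the mask convexified. Convexification matters: a dark lesion
sitting on the FOV boundary otherwise carves a notch out of the mask and
is whited out of the calibrated image. The **border ring** is the mask
minus its erosion (disc radius 3 — thin, so rim lesions lose little area).
The **calibrated image** adds 255 outside the mask and on the ring
(saturating), making rim lesions dark objects on a bright surround. The
**search space S** dilates the mask by an 80 px margin (Euclidean distance
transform), bounding all window growth.

Seed extraction runs on the *calibrated* image: on a near-black frame
(< 10 gray levels) a rim lesion has no bright surround and hence no
matched-filter response; whitening the background first restores the
dark-blob profile the filter is tuned to. This is the same reasoning the
calibration stage exists for; it simply has to precede seeding as well as
segmentation.

### SWAT segmentation

Per window, the gray-level histogram (256 bins) is partitioned into R
regions by maximizing the between-region variance
`σ_B² = Σ_z ω_z (μ_z − μ_T)²` over strictly increasing threshold tuples
(the multilevel extension of Otsu's criterion). R grows 2, 3, … until the
effectiveness `η = σ_B²/σ_T²` reaches 0.8 or R caps at 20. The darkest
stratum (pixels ≤ min threshold, inclusive) becomes foreground. Among its
8-connected components, the two largest are kept and the one whose minimum
Euclidean pixel distance to the window center is smaller is selected
(seeds come from a filter tuned to lesion centers, so centrality is
evidence). Window sides touched by the selected object move outward —
left/top by 5 px, right/bottom by 10 px, as specified — provided every
pixel of the moved edge lies inside S; the loop stops when no side moves
or after 50 iterations (the object is then flagged non-converged).
Objects from different seeds whose masks overlap at IoU > 0.8 are
collapsed to the larger one.

Numerical choices:

- The optimal partition is found **exhaustively** (vectorized over all
  tuples) whenever the tuple count is ≤ 120 000, otherwise by a
  contiguous-partition **dynamic program on the occupied gray levels**
  (value `Σ S_z²/W_z`, O(R·K²) for K occupied levels).
- Ties are resolved to the lexicographically smallest tuple. Because two
  thresholds inside the same unoccupied gap induce the *identical*
  partition yet can produce float scores differing in the last bits
  (summation order), tuples within 10⁻⁹ relative of the float maximum are
  re-compared in exact rational arithmetic over the integer counts.
- When each region holds exactly one occupied level the partition
  explains all variance and η is set to 1.0 identically.
- `ω_z = 0` regions contribute zero to σ_B² with μ_z defined as 0.
- The initial window is the seed bounding box expanded by **12 px per
  side** (`seed_pad`). Without the pad, a seed core lying wholly inside a
  large uniform lesion yields a window with no bright surround; its
  histogram is pure noise, the darkest stratum is a few-pixel speck, no
  border flag raises, and the loop "converges" to a degenerate object.
  A window that sees some surround thresholds correctly and then grows to
  the lesion's true extent.

### Features and classification

Five conventional blocks per candidate (local patch = mask bounding box +
8 px): shape (area, perimeter, circularity 4πA/P², eccentricity, solidity,
extent, axis ratio — separating line-like vessels from round lesions);
boundary edge strength (mean/max |Laplacian| and Sobel magnitude on the
object's boundary ring — lesions have sharper rims than the macula);
masked-GLCM texture (contrast, correlation, energy, homogeneity at 32
levels, plus intensity variance and entropy); color (per-channel mean/std,
mean HSV, object-vs-surround ratios over a 5 px dilation ring — separating
reddish blood from gray illumination shades); and contour hand-crafted
features (closedness, curvature-maxima corner count at a 0.9 rad turning
threshold, corner-to-centroid distance mean/std). Blocks that fail on a
degenerate region carry a 0 sentinel plus a per-block missing indicator.

A deep-feature interface (`FeatureExtractor`) is provided for CNN
hidden-layer backends; none ships with the core, and requesting an
unregistered one raises a capability error without affecting the
conventional path.

Candidates are annotated against ground truth by **IoU ≥ 0.2 with any
truth lesion component**; the threshold is deliberately loose because
window masks are tight while truth ellipses are coarse. An RBF-kernel SVM
is trained on z-normalized features (scaler statistics stored with the
model, feature-name order checked at prediction time); C ∈ {0.1, 1, 10,
100} × γ ∈ {auto, 0.01, 0.1} are selected on a validation split by
SE + SP. Splits are image-level (no window crosses splits), with
fractions 0.5/0.2/0.3 train/validation/test.

## The synthetic data generator

All development and testing runs on generated fundus-like images with
pixel-accurate ground truth. Defaults (the study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| frame | 512×512 px | 50°-FOV geometry scaled down from the 1500×1152 class so a 30-image study runs in minutes |
| FOV radius | 0.92 of the inscribed circle | thin black frame all around |
| illumination | radial vignette + random linear gradient, strength 0.3 | "uneven illumination" of real fundus photographs |
| background texture | multiplicative Gaussian mottle, σ 12 gray levels, correlation 24 px | choroidal texture; keeps windows from being artificially clean |
| dark shades | 3 soft elliptical decoys, depth 0.25, radius 25–50 px | the gray illumination shades that mislead detection; the non-HE class the classifier must reject |
| vessels | 8 random-walk polylines from rim toward center, widths 2–5 px, green-channel darkening ×0.80 | see below |
| hemorrhages | 6 rotated perturbed ellipses, semi-major 10–22 px, green darkening ×0.30 | "comparatively circular" dark objects |
| vessel-attached fraction | 0.3 | the paper-highlighted hard class |
| border-touching fraction | 0.2 | ditto; placed with the outer lip crossing the FOV boundary |
| pixel noise | σ 2 gray levels | sensor noise |

The vessel darkening factor (0.80 of retina, versus 0.30 for lesions)
encodes the partial-volume argument: a 2–5 px vessel averages with
surrounding tissue over the camera's point-spread function, while a pooled
hemorrhage does not. This is also the regime in which the darkest-stratum
rule can work at all: when vessels are rendered as dark as lesions, the
R=2 variance-maximizing cut always groups an adjoined lesion with its
vessel (splitting dark-vs-retina explains more variance than splitting
lesion-vs-vessel at any η ≥ 0.8 stopping point), and no parameter of the
method separates them. The generator therefore represents vessels as
moderately dark, which real thin vessels are; *equal-intensity*
vessel-lesion complexes remain a stated limitation.

What the generator does **not** emulate: optic disc and macula anatomy,
vessel central light reflex and caliber hierarchy, exudates and
microaneurysms, JPEG artifacts, and the intensity statistics of any real
camera. Passing tests therefore demonstrate that the implementation
realizes the method's mechanics and that the method behaves as designed
under its own photometric assumption — not clinical performance on real
photographs.

## Verification

The test suite checks, among others: exact agreement of the multilevel
threshold with an exhaustive rational-arithmetic oracle on random
histograms (L ≤ 32, R ≤ 4); η ∈ [0, 1], monotone in R, and exactly 1 for
R-valued histograms; the stopping rule returning the first η ≥ 0.8
crossing; the window primitives against brute-force oracles; planted-lesion
recovery (IoU ≥ 0.7 for ≥ 90% of lesions over 20 default-condition images,
with every lesion class represented); an end-to-end 30-image study
reaching SE ≥ 85% and SP ≥ 85% on held-out images with a label-permutation
control collapsing to chance; and byte-identical CSV/JSON outputs across
repeated runs. `scripts/acceptance.py` recomputes these quantities from
scratch on fresh seeds. Problem sizes (20 and 30 images of 512²) are the
package's chosen study scale.

## Known limitations

- A hemorrhage whose intensity equals that of an adjoining vessel cannot
  be separated by any intensity stratum; such complexes segment as one
  object.
- Windows seeded on the dark band just inside the rim (vignette) can drift
  along it: the white background dominates the R=2 cut, so the band joins
  the darkest stratum and keeps the border flags raised. The search space
  bounds, but does not prevent, such drift; affected rim lesions
  (~10–15% of the border-touching class under default conditions) are
  recovered only partially.
- The GLCM entropy threshold always keeps a top response tail, so
  lesion-free images still produce candidate windows; rejecting them is
  the classifier's job.
- The η ≥ 0.8 stopping rule is coarse on strongly bimodal windows: it can
  stop at R = 2 before a stratum boundary that would separate two dark
  structures exists. This is inherent to the stopping statistic, not to
  the implementation.
- All quantitative results are on synthetic data; no claim is made about
  DIARETDB1-class photographs.
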