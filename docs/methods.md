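# Methods

## The measurement problem

Leaf area index (LAI, m² of one-sided leaf area per m² of ground) is the
workhorse descriptor of canopy structure, but direct measurement means
defoliating trees. Digital cover photography estimates it optically: an
upward-looking, narrow-field photograph of the canopy taken from below, in
which every pixel is either foliage or visible sky. `canopylai` implements
this analysis for fruit-tree (orchard) canopies, where foliage is strongly
clumped into discrete crowns and the light extinction coefficient varies
enough between trees that treating it as a constant is the dominant error
source.

## Image analysis

**Blue-band segmentation.** Only the blue channel (450–495 nm) is used:
leaves reflect little blue light while sky and clouds are bright in it, so
the blue histogram of an upward-looking photo is bimodal and clouds fall on
the sky side without any separate cloud classifier. The foliage/sky
threshold is found automatically as the minimum of the smoothed histogram
between its two dominant modes:

* smoothing: centered moving average over 9 intensity bins (configurable,
  odd). The 256-bin histogram of a single photo is noisy; a one-bin spike
  between the modes should not capture the valley.
* modes: the two highest local maxima of the smoothed histogram at least
  10 intensity levels apart. A flat valley resolves to the midpoint of the
  minimal plateau, which makes the threshold deterministic and independent
  of scan order.
* classification: blue ≥ threshold ⇒ sky. The threshold intensity itself
  belongs to the bright (sky) class.
* fallback: if no two separated modes exist (fog, uniform overcast), the
  split maximizing between-class variance (Otsu's criterion, computed from
  the histogram) is used and a `ThresholdFallbackWarning` is emitted.
  Histogram-valley thresholding is undefined for unimodal histograms, so
  some deterministic rule is needed; Otsu's is the standard one.

**Gap analysis.** The binary mask is tiled into `subdivision²` rectangular
sub-images (default 7, i.e. 49 per photo and 196 per four-photo tree).
Frame sizes not divisible by the subdivision are tiled near-equally
(block sizes differ by at most one pixel) so that every pixel is counted
exactly once — the cover equations below implicitly require the tile sums
to add up to the total pixel count. Per sub-image, S = sky pixels and
L = leaf pixels; the sub-image's sky is counted as *large gap* (sky between
crowns rather than within them) when S/L > 0.75 (strict inequality;
configurable) or when L = 0, the natural reading of the ratio rule for
pure-sky regions. From the totals g_T (gap), g_L (large gap) and T_P
(all pixels):

    f_f = 1 − g_T/T_P        foliage cover
    f_c = 1 − g_L/T_P        crown cover

g_L ⊆ g_T guarantees f_f ≤ f_c. Counts stay integers until the final
division.

## Canopy structure and LAI

    Φ    = 1 − f_f/f_c                                   crown porosity
    Ω(0) = (1 − Φ)·ln(1 − f_f) / (ln(Φ)·f_f)             zenith clumping index
    LAI  = −f_c · (ln(Φ)/k) · Ω(0)                       Beer's law, clumped
    k_M  = −f_c · (ln(Φ)/LAI_D) · Ω(0)                   inversion vs. ground truth

with k the light extinction coefficient and LAI_D a destructively measured
LAI (leaf mass × specific leaf area / ground area per tree). All logs are
natural. Ω(0) ∈ (0, 1] penalizes the aggregation of foliage into crowns;
when the crown envelope fills the frame (f_c = 1, Φ = 1 − f_f) it equals 1
and the expression reduces to the classic Beer's-law inversion
LAI = −ln(1 − f_f)/k.

One algebraic property is worth stating because the tests rely on it: when
Ω(0) is taken from its defining expression above, it cancels against ln(Φ)
and the LAI formula collapses to −ln(1 − f_f)/k exactly. The f_c/Φ/Ω(0)
decomposition carries information (and is reported per tree) but the final
LAI of this estimator is driven by foliage cover and k alone; this is also
why `invert_k` is an exact inverse and why LAI scales exactly as 1/k.

**Degenerate inputs.** f_f = 0 ⇒ LAI = 0 by definition. Φ = 0 (no
within-crown gaps) and f_f → 1 saturate the inversion; below Φ = 1e-9 the
implementation switches to the algebraically equivalent Φ-free form
−f_c·(1−Φ)·ln(1−f_f)/(k·f_f) with a `SaturationWarning`, avoiding the
0·∞ product. Fractions are validated to [0, 1] with 1e-9 tolerance;
violations beyond it raise rather than clamp silently.

**Sensitivity to k.** Because LAI ∝ 1/k, a relative perturbation δ of k
changes LAI by exactly 100·(1/(1+δ) − 1) %, independent of the canopy:
+30% → −23.1%, −30% → +42.9%. `k_sensitivity` returns this closed form;
tests confirm it against empirical perturbation.

## Extinction-coefficient schemes

1. **constant_k** — one k for all images; default 0.68, the mean measured
   for apple. (0.5 is the common eucalyptus value, 0.7 grapevine.)
2. **k_from_ff** — k predicted from foliage cover, exponential
   k = a·exp(b·f_f) or linear k = a·f_f + b. Shipped presets are the apple
   calibrations (whole dataset: 0.136·exp(1.99·f_f), and per-site variants);
   these are site- and cultivar-specific and must be refitted elsewhere.
3. **k_from_ic** — k proxied by the intercepted light fraction
   I_c = 1 − mean(I)/I_o from ceptometer PAR readings, k = slope·I_c with
   default slope 0.99 (the fitted through-origin relation is essentially
   the 1:1 line). This auto-calibrates per tree and is the most accurate
   scheme, at the cost of one extra instrument.

**Fitting.** The exponential k(f_f) model is fitted by least squares of
ln(k) on f_f and back-transformed; its r² is therefore on the log scale.
Log-linear fitting was chosen over iterative nonlinear least squares
because it is deterministic, closed-form and adequate for the ~10%
multiplicative scatter these calibrations show. The through-origin
k(I_c) slope is Σxy/Σx², with r² = 1 − SS_res/Σy² (total sum of squares
about zero, since the model has no intercept).

## Validation statistics

RMSE, MAE, MBE (predicted − observed convention: positive MBE =
overestimation), Willmott's index of agreement in its original
squared-difference form

    d = 1 − Σ(P−O)² / Σ(|P−Ō| + |O−Ō|)²,   Ō = mean(O)

(the standard skill score in the agro-meteorology literature), and the r²
of OLS of predicted on observed. Percent errors divide by the mean observed
value. The regression check fits predicted on observed and runs two-sided
t-tests (n−2 dof) of intercept = 0 and slope = 1 at α = 0.05.

## Synthetic fixtures

`render_scene` rasterizes elliptical crown blobs on a sky background.
Within-crown porosity is realised by flipping an *exact count* of seeded
random interior pixels to sky, so the reported ground-truth fractions are
exact pixel tallies, not expectations — this is what makes bit-exact
pipeline-recovery tests possible. Foliage and sky blue tones live in
disjoint ranges ([10, 60] vs [150, 220] by default); optional Gaussian tone
noise is truncated to each class range so the classes can never overlap.
The default scene is 512×384, the 4:3 aspect of a 2048×1536 camera frame
scaled down 4× to keep tests fast.

What the scenes emulate: the binary geometry of crowns and gaps, the
bimodal blue histogram, the four-quadrant-per-tree protocol. What they do
not: penumbra and mixed pixels at leaf edges, exposure variation, clouds
with intermediate brightness, branches and fruit. Passing recovery tests
therefore demonstrates correctness of the gap-analysis arithmetic and
thresholding on separable scenes, not robustness of segmentation on real
photographs.

`simulate_beer_law_dataset` draws per-tree (f_f, f_c) uniformly from
f_f ∈ [0.6, 0.9], f_c ∈ [0.75, 1.0] with f_f ≤ f_c — the range mature
apple orchards show — derives Φ and Ω(0), assigns k from a chosen model
(default the whole-dataset exponential) with multiplicative lognormal noise,
sets LAI from Beer's law exactly and I_c = k/slope. Noise draws implying
I_c > 1 are redrawn (a truncation, negligible at the default 10% noise),
keeping records inside the valid domain of the interception proxy. An
optional jitter parameter loosens the exact I_c–k tie for robustness tests.

## Pipeline conventions

* Images are grouped into trees by filename, default `<tree>_<quadrant>.<ext>`
  with quadrant 1–4; the pattern is a configurable regex. Trees with ≠ 4
  photos are processed with a warning.
* Per-tree metrics default to **pooled pixel counts** over the tree's
  images (the 196-sub-image reading of the protocol); per-image LAI
  averaging is available as `aggregation = per_image_mean`.
* Output CSVs use fixed 6-significant-digit floats and stable row order,
  so re-runs on identical inputs are byte-identical.
* With a ground-truth table the pipeline also reports k_M per tree and the
  full statistics block.

## Problem sizes

Tests and the acceptance script run entirely on synthetic data: orchards of
10 trees × 4 quadrants at 512×384 px, 100+ random masks for oracle
equivalence, 1000 tuples for the inversion roundtrip, and n = 200 records
for calibration-recovery fits — sizes chosen to exercise every code path
at comfortable desk scale.

## Known limitations

* No woody-area correction: branches and fruit in real images count as
  foliage, inflating f_f (real calibrations absorb this into k).
* Zenith-only: no angular gap-fraction inversion or leaf-angle model.
* The blue-band valley threshold assumes a bimodal histogram; heavy fog or
  uniform overcast falls back to Otsu with a warning.
* The k(f_f) presets are calibrations for specific orchards; using them on
  other species or densities is unsupported extrapolation (the linear
  presets go negative at low cover and raise).
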